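"""Hammerhead pairing topology, heavy-atom accounting, WC detection,
heterochiral construction and restrained refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirrorhh import RIBOZYME_33NT, SUBSTRATE_14NT
from mirrorhh.compare_analyze import kabsch_superpose
from mirrorhh.complex_model import (
    RefinementSettings,
    TopologyError,
    build_heterochiral,
    count_heavy_atoms,
    detect_wc_pairs_3d,
    find_cleavage_sites,
    hammerhead_pairing,
    restrained_refine,
)
from mirrorhh.restraints import build_restraints
from mirrorhh.synthetic import A_FORM, build_duplex, perturb


# ---------------------------------------------------------------------------
# cleavage-site scan
# ---------------------------------------------------------------------------

def test_cleavage_site_of_the_substrate(substrate_seq):
    assert find_cleavage_sites(substrate_seq) == [9]


@pytest.mark.parametrize("seq,expected", [
    ("AAAA", []),
    ("GUCGUCA", [3, 6]),
    ("GUC", []),          # no following nucleotide
    ("AGUCA", [4]),
])
def test_cleavage_site_examples(seq, expected):
    assert find_cleavage_sites(seq) == expected


@given(st.text(alphabet="ACGU", min_size=0, max_size=30))
@settings(max_examples=200, deadline=None)
def test_cleavage_scan_matches_brute_force(seq):
    brute = [i + 3 for i in range(len(seq))
             if seq[i:i + 3] == "GUC" and i + 3 < len(seq)]
    assert find_cleavage_sites(seq) == brute


# ---------------------------------------------------------------------------
# pairing topology
# ---------------------------------------------------------------------------

def test_helix1_and_helix3_residue_ranges(pairing):
    h1 = {(p.res_a, p.res_b) for p in pairing.helix_pairs("H1")}
    assert h1 == {(("S", 14 - k), ("R", 1 + k)) for k in range(5)}
    h3 = {(p.res_a, p.res_b) for p in pairing.helix_pairs("H3")}
    assert h3 == {(("S", 8 - k), ("R", 28 + k)) for k in range(6)}


def test_helix2_is_four_gc_pairs_closing_a_gaaa_loop(pairing, ribozyme_seq):
    h2 = pairing.helix_pairs("H2")
    assert len(h2) == 4
    assert all(p.pair_type == "G-C" for p in h2)
    paired = {i for p in h2 for (_c, i) in p.residues()}
    lo, hi = max(i for i in paired if i < 20), min(i for i in paired if i > 17)
    loop = ribozyme_seq[lo:hi - 1]
    assert loop == "GAAA"
    assert all(("R", i) in pairing.unpaired for i in range(lo + 1, hi))


def test_cleavage_site_recorded_and_unpaired(pairing):
    assert pairing.cleavage_site == ("S", 9)
    assert ("S", 9) in pairing.unpaired


def test_mutated_substrate_raises_topology_error(ribozyme_seq, substrate_seq):
    mutated = substrate_seq[:13] + "U"        # A14 -> U
    with pytest.raises(TopologyError, match="14"):
        hammerhead_pairing(ribozyme_seq, mutated)


def test_zero_or_multiple_guc_sites_raise(ribozyme_seq):
    with pytest.raises(TopologyError, match="GUC"):
        hammerhead_pairing(ribozyme_seq, "AAAAAAAAAAAAAA")
    with pytest.raises(TopologyError, match="GUC"):
        hammerhead_pairing(ribozyme_seq, "GUCAAGUCCGCCAA")


def test_dot_bracket_export(pairing, ribozyme_seq, substrate_seq):
    dbn = pairing.to_dot_bracket(len(ribozyme_seq), len(substrate_seq))
    rz, sub = dbn.split("&")
    assert len(rz) == 33 and len(sub) == 14
    assert rz.count("(") == rz.count(")") == 4
    assert rz.count("[") == sub.count("]") == 11


# ---------------------------------------------------------------------------
# heavy-atom accounting
# ---------------------------------------------------------------------------

def test_printed_atom_totals(ribozyme_seq, substrate_seq):
    assert count_heavy_atoms(substrate_seq) == 289
    assert count_heavy_atoms(ribozyme_seq) == 711
    assert count_heavy_atoms([substrate_seq, ribozyme_seq]) == 1000


def test_single_g_with_terminal_phosphate():
    assert count_heavy_atoms("G", five_prime_phosphate=True) == 23


def test_count_matches_built_structures(scaffold, a_duplex):
    assert count_heavy_atoms(scaffold) == scaffold.atom_count()
    assert count_heavy_atoms(a_duplex) == a_duplex.atom_count()
    for chain in scaffold.chains:
        assert count_heavy_atoms(chain) == sum(len(r.atoms) for r in chain)


# ---------------------------------------------------------------------------
# 3D WC detection
# ---------------------------------------------------------------------------

def test_separated_strands_have_no_pairs(a_duplex):
    moved = a_duplex.copy()
    for res in moved.chains[1].residues:
        res.set_coords({n: res[n] + np.array([20.0, 0, 0])
                        for n in res.atom_names()})
    assert detect_wc_pairs_3d(moved) == []


def test_heterochiral_complex_pair_classes(hetero_ld, pairing):
    detected = {frozenset(p.residues()): p for p in detect_wc_pairs_3d(hetero_ld)}
    for p in pairing.pairs:
        key = frozenset(p.residues())
        assert key in detected, f"pair {p.res_a}-{p.res_b} lost"
        expected = "homochiral" if p.helix == "H2" else "heterochiral"
        assert detected[key].chirality_class == expected


# ---------------------------------------------------------------------------
# heterochiral construction
# ---------------------------------------------------------------------------

def test_enantiomerized_bases_stay_anchored(scaffold, pairing):
    """Before refinement, each mirrored residue's base superposes onto its
    original position (planar bases are achiral)."""
    dd = scaffold
    het = build_heterochiral(dd, "S", pairing, refine=False)
    for ra, rb in zip(dd.chain("S").residues, het.chain("S").residues):
        names = ra.base_atom_names()
        rmsd = float(np.sqrt(np.mean(np.sum(
            (ra.coords(names) - rb.coords(names)) ** 2, axis=1))))
        assert rmsd < 0.1


def test_heterochiral_verdict_and_involution(refined_dd, hetero_ld, pairing):
    from mirrorhh.chirality import validate_chirality
    assert validate_chirality(hetero_ld).verdict == "mixed"
    restored = build_heterochiral(hetero_ld, "S", pairing)
    assert validate_chirality(restored).verdict == "all-D"


def test_heterochiral_requires_pairing(refined_dd):
    dd, _ = refined_dd
    with pytest.raises(ValueError, match="PairingMap"):
        build_heterochiral(dd, "S", None)


# ---------------------------------------------------------------------------
# restrained refinement
# ---------------------------------------------------------------------------

def _duplex_pairing(dup):
    """All inter-chain pairs of an ideal duplex as a pairing-like list."""
    from mirrorhh.complex_model import BasePair, PairingMap
    n = len(dup.chains[0])
    pairs = [BasePair(("A", i + 1), ("B", n - i),
                      "G-C" if dup.chains[0].residues[i].code in "GC" else "A-U")
             for i in range(n)]
    return PairingMap(pairs=pairs)


def test_refine_ideal_duplex_is_already_at_minimum():
    dup = build_duplex("GACU", A_FORM, chain_ids=("A", "B"))
    pm = _duplex_pairing(dup)
    refined, trace = restrained_refine(dup, pm)
    assert trace[0] - trace[-1] < 1e-6
    assert np.max(np.abs(refined.coords() - dup.coords())) < 1e-3


def test_refine_restores_stretched_hydrogen_bond():
    dup = build_duplex("AU", A_FORM)
    pm = _duplex_pairing(dup)
    # stretch the A1-U2' pair by displacing the partner base along the bond
    res_a = dup.chain("A").residues[0]
    res_b = dup.chain("B").residue(2)
    direction = res_b["N3"] - res_a["N1"]
    direction /= np.linalg.norm(direction)
    target_gap = 3.5 - float(np.linalg.norm(res_b["N3"] - res_a["N1"]))
    res_b.set_coords({n: res_b[n] + target_gap * direction
                      for n in res_b.atom_names()})
    assert np.linalg.norm(res_b["N3"] - res_a["N1"]) == pytest.approx(3.5, abs=1e-6)
    refined, trace = restrained_refine(dup, pm,
                                       RefinementSettings(steps=4000))
    d = float(np.linalg.norm(refined.chain("B").residue(2)["N3"]
                             - refined.chain("A").residues[0]["N1"]))
    assert abs(d - 2.9) < 0.05
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))


def test_refine_zero_steps_is_identity(a_duplex):
    refined, trace = restrained_refine(a_duplex, _duplex_pairing(a_duplex),
                                       RefinementSettings(steps=0))
    assert np.array_equal(refined.coords(), a_duplex.coords())
    assert len(trace) == 1


def test_refinement_energy_trace_monotone_on_scaffold(refined_dd):
    _, trace = refined_dd
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))


def test_restraint_gradient_matches_finite_differences():
    """Analytic gradients (bonds, angles, planarity, chirality, anchors)
    agree with central finite differences."""
    dup = perturb(build_duplex("GC", A_FORM), 0.08, seed=2)
    pm = _duplex_pairing(dup)
    anchors = [("A", 1, "N9", dup.chain("A").residues[0]["N9"] + 0.3)]
    rset = build_restraints(dup, pm, anchor_atoms=anchors)
    x0 = dup.coords().reshape(-1)
    e0, g = rset.energy_and_gradient(x0)
    rng = np.random.default_rng(0)
    idxs = rng.choice(len(x0), size=24, replace=False)
    h = 1e-6
    for i in idxs:
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        num = (rset.energy_and_gradient(xp)[0]
               - rset.energy_and_gradient(xm)[0]) / (2 * h)
        assert num == pytest.approx(g[i], rel=1e-4, abs=1e-5)
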