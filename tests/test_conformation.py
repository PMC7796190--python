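"""Dihedrals, glycosidic chi, pseudorotation and pucker classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirrorhh import conformation as cf
from mirrorhh._geom import rotation_about_axis
from mirrorhh.chirality import mirror_structure
from mirrorhh.templates import ring_torsions


@pytest.mark.parametrize("p4,expected", [
    ((1, -1, 0), 180.0),   # trans planar
    ((1, 1, 0), 0.0),      # cis planar
    ((1, 0, 1), 90.0),     # positive = clockwise viewed p2 -> p3
])
def test_dihedral_sign_convention(p4, expected):
    assert cf.dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), p4) == pytest.approx(expected)


def test_dihedral_degenerate_bond_raises():
    with pytest.raises(ValueError, match="degenerate"):
        cf.dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_dihedral_rigid_motion_invariance(seed):
    """Torsions are invariant under proper rotation + translation."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(4, 3))
    try:
        ref = cf.dihedral(*pts)
    except ValueError:
        return
    R = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 360))
    t = rng.normal(size=3)
    moved = pts @ R.T + t
    assert cf.dihedral(*moved) == pytest.approx(ref, abs=1e-9)


def test_backbone_torsions_terminal_absences(a_duplex):
    chain = a_duplex.chains[0]
    rows = cf.backbone_torsions(chain)
    assert rows[0]["alpha"] is None and rows[0]["beta"] is None  # 5'-OH terminus
    assert rows[-1]["epsilon"] is None and rows[-1]["zeta"] is None
    interior = rows[1]
    assert all(interior[k] is not None for k in interior)


def test_a_form_gamma_and_chi_regression(a_duplex):
    """Pinned generator values: gamma gauche+ (~54), chi anti (~-160)."""
    rows = cf.backbone_torsions(a_duplex.chains[0])
    gammas = [r["gamma"] for r in rows]
    assert all(20.0 < g < 90.0 for g in gammas)          # gauche+
    assert gammas[1] == pytest.approx(44.66, abs=0.5)    # frozen template value
    chi = cf.glycosidic_chi(a_duplex.chains[0].residues[0])
    assert -175.0 < chi < -140.0                          # anti, near -160
    assert chi == pytest.approx(-161.43, abs=0.5)         # frozen template value


def test_mirrored_chain_negates_every_defined_torsion(a_duplex):
    mirrored = mirror_structure(a_duplex)
    for ch_a, ch_b in zip(a_duplex.chains, mirrored.chains):
        for ra, rb in zip(cf.backbone_torsions(ch_a), cf.backbone_torsions(ch_b)):
            for key in ra:
                if ra[key] is None:
                    assert rb[key] is None
                else:
                    dev = (ra[key] + rb[key]) % 360.0
                    assert min(dev, 360.0 - dev) < 1e-9


def test_chi_missing_atoms_is_incomplete_residue_error(a_duplex):
    res = a_duplex.chains[0].residues[0].copy()
    del res.atoms["C1'"]
    with pytest.raises(ValueError, match="incomplete residue"):
        cf.glycosidic_chi(res)


@pytest.mark.parametrize("chi,expected", [
    (-158.0, "anti"), (65.0, "syn"), (90.0, "anti"), (-90.0, "anti"),
    (89.9, "syn"), (200.0, "anti"),
])
def test_syn_anti_classification(chi, expected):
    assert cf.classify_syn_anti(chi) == expected


@pytest.mark.parametrize("P0,vmax", [(18.0, 38.0), (162.0, 38.0), (300.0, 41.0)])
def test_pseudorotation_inverts_generating_formula(P0, vmax):
    """nu_j = vmax*cos(P + 144(j-2)) must invert to exactly (P, vmax)."""
    nus = ring_torsions(P0, vmax)
    P, v = cf.pseudorotation_from_nus(nus)
    assert P == pytest.approx(P0, abs=1e-9)
    assert v == pytest.approx(vmax, abs=1e-9)
    assert nus[2] == pytest.approx(v * np.cos(np.radians(P)), abs=1e-6)


def test_flat_ring_has_undefined_phase():
    P, v = cf.pseudorotation_from_nus(np.zeros(5))
    assert P is None and v == 0.0
    with pytest.raises(ValueError):
        cf.classify_pucker(P)


def test_mirrored_residue_phase_shifts_180(a_duplex):
    mirrored = mirror_structure(a_duplex)
    for ra, rb in zip(a_duplex.residues(), mirrored.residues()):
        Pa, va = cf.pseudorotation(ra)
        Pb, vb = cf.pseudorotation(rb)
        dev = (Pb - Pa - 180.0) % 360.0
        assert min(dev, 360.0 - dev) < 1e-9
        assert vb == pytest.approx(va, abs=1e-9)


@pytest.mark.parametrize("P,klass,name", [
    (18.0, "N", "C3'-endo"),
    (162.0, "S", "C2'-endo"),
    (90.0, "other", "O4'-endo"),
    (315.0, "N", "1T2"),
    (100.0, "other", "0T1"),
])
def test_pucker_classification(P, klass, name):
    got_klass, got_name = cf.classify_pucker(P)
    assert got_klass == klass
    assert got_name == name


def test_phosphate_distances(a_duplex, b_duplex):
    dists_a = cf.phosphate_distances(a_duplex.chains[0])
    dists_b = cf.phosphate_distances(b_duplex.chains[0])
    assert np.allclose(dists_a, 5.9, atol=0.15)
    assert np.allclose(dists_b, 7.0, atol=0.15)
    single = a_duplex.chains[0].residues[:1]
    from mirrorhh.structure_io import RNAChain
    assert cf.phosphate_distances(RNAChain("X", [r.copy() for r in single])) == []


def test_ring_torsion_reconstruction_consistency(a_duplex, b_duplex):
    """(P, vmax) reproduce the five measured ring torsions within the
    Altona-Sundaralingam approximation bound (1.5 deg) on built sugars."""
    for cx in (a_duplex, b_duplex):
        for res in cx.residues():
            nus = cf.ring_nu_torsions(res)
            P, vmax = cf.pseudorotation_from_nus(nus)
            model = ring_torsions(P, vmax)
            assert np.max(np.abs(nus - model)) < 1.5


def test_records_to_frame_shape(a_duplex):
    df = cf.records_to_frame(cf.complex_records(a_duplex))
    assert len(df) == sum(len(c) for c in a_duplex.chains)
    assert {"chain", "residue", "chi", "P", "pucker_class"} <= set(df.columns)
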