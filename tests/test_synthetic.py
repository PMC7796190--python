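"""Generators: ideal duplexes, the hammerhead scaffold, perturbation and
seeded conformational ensembles."""

import numpy as np
import pytest

from mirrorhh.chirality import mirror_structure
from mirrorhh.compare_analyze import conformer_distribution, rmsd_selection
from mirrorhh.complex_model import detect_wc_pairs_3d
from mirrorhh.conformation import complex_records, phosphate_distances, records_to_frame
from mirrorhh.structure_io import ModelEnsemble
from mirrorhh.synthetic import (
    A_FORM,
    B_FORM,
    EnsembleSpec,
    GenerationError,
    build_duplex,
    build_hammerhead_scaffold,
    generate_ensemble,
    perturb,
    reverse_complement,
)


def test_duplex_strand2_is_reverse_complement(a_duplex):
    from mirrorhh.structure_io import sequence_of
    s1 = sequence_of(a_duplex.chains[0])
    s2 = sequence_of(a_duplex.chains[1])
    assert s2 == reverse_complement(s1)


@pytest.mark.parametrize("form,target", [(A_FORM, 5.9), (B_FORM, 7.0)])
def test_duplex_adjacent_pp_distance(form, target):
    dup = build_duplex("GGGGGG", form)
    for chain in dup.chains:
        mean = float(np.mean(phosphate_distances(chain)))
        assert abs(mean - target) < 0.15


def test_duplex_every_pair_detected_and_homochiral(a_duplex):
    pairs = detect_wc_pairs_3d(a_duplex)
    assert len(pairs) == len(a_duplex.chains[0])
    assert all(p.chirality_class == "homochiral" for p in pairs)
    gc = build_duplex("GC", A_FORM)
    assert len(detect_wc_pairs_3d(gc)) == 2


@pytest.mark.parametrize("form,klass", [(A_FORM, "N"), (B_FORM, "S")])
def test_duplex_sugars_in_target_pucker(form, klass):
    dup = build_duplex("GACU", form)
    df = records_to_frame(complex_records(dup))
    assert set(df["pucker_class"]) == {klass}


def test_duplex_all_residues_D(a_duplex, b_duplex):
    for dup in (a_duplex, b_duplex):
        assert {r.chirality for r in dup.residues()} == {"D"}


def test_duplex_rejects_bad_sequence():
    with pytest.raises(ValueError):
        build_duplex("ACGT")  # T is DNA
    with pytest.raises(ValueError):
        build_duplex("A")


def test_generator_determinism():
    d1 = build_duplex("GAC", A_FORM)
    d2 = build_duplex("GAC", A_FORM)
    assert np.array_equal(d1.coords(), d2.coords())


def test_scaffold_composition(scaffold, pairing):
    assert sum(len(c) for c in scaffold.chains) == 47
    assert scaffold.atom_count() == 1000
    assert {r.chirality for r in scaffold.residues()} == {"D"}
    detected = {frozenset(p.residues()) for p in detect_wc_pairs_3d(scaffold)}
    wanted = {frozenset(p.residues()) for p in pairing.pairs}
    assert wanted <= detected


def test_scaffold_respects_clash_floor(scaffold):
    from scipy.spatial import cKDTree
    recs = list(scaffold.atom_records())
    xyz = np.array([a.position for _, _, a in recs])
    keys = [(c.chain_id, r.index) for c, r, _ in recs]
    bad = [
        (keys[i], keys[j])
        for i, j in cKDTree(xyz).query_pairs(r=2.5)
        if keys[i] != keys[j]
        and not (keys[i][0] == keys[j][0] and abs(keys[i][1] - keys[j][1]) == 1)
    ]
    assert bad == []


def test_scaffold_index_error_for_out_of_range_pairing(ribozyme_seq, substrate_seq,
                                                       pairing):
    with pytest.raises(IndexError):
        build_hammerhead_scaffold(ribozyme_seq, substrate_seq[:8], pairing)


def test_perturb_contracts(a_duplex):
    assert np.array_equal(perturb(a_duplex, 0.0, 1).coords(), a_duplex.coords())
    p1 = perturb(a_duplex, 0.1, seed=42)
    p2 = perturb(a_duplex, 0.1, seed=42)
    assert np.array_equal(p1.coords(), p2.coords())
    with pytest.raises(ValueError):
        perturb(a_duplex, -0.1, 1)


def test_perturb_rmsd_matches_sigma_sqrt3(a_duplex):
    """RMSD of i.i.d. Gaussian displacement concentrates at sigma*sqrt(3)."""
    sigma = 0.25
    rmsds = [rmsd_selection(a_duplex, perturb(a_duplex, sigma, seed=s),
                            superpose=False)[0] for s in range(5)]
    n = a_duplex.atom_count()
    tol = 4.0 * sigma * np.sqrt(3.0 / (2.0 * n))  # ~4 sd of the chi distribution
    assert abs(float(np.mean(rmsds)) - sigma * np.sqrt(3)) < tol


def test_ensemble_spec_validation():
    with pytest.raises(ValueError):
        EnsembleSpec(n_models=0)
    with pytest.raises(ValueError):
        EnsembleSpec(n_models=1, p_sd=-1.0)
    spec = EnsembleSpec.from_json('{"n_models": 2, "p_mean": 18.0, "seed": 3}')
    assert spec.n_models == 2 and spec.seed == 3


def test_degenerate_ensemble_hits_prescribed_phase_exactly():
    dup = build_duplex("GC", A_FORM)
    ens = generate_ensemble(dup, EnsembleSpec(n_models=3, p_mean=162.0, p_sd=0.0,
                                              chi_mean=-120.0, chi_sd=0.0, seed=9))
    df = records_to_frame(complex_records(ens[0]))
    assert np.max(np.abs(df["P"] - 162.0)) < 1.0
    assert np.max(np.abs(df["chi"] + 120.0)) < 1e-6


def test_ensemble_parameter_recovery_200_frames():
    """Prescribed P/chi distributions are recovered within sampling error."""
    dup = build_duplex("GC", A_FORM)
    spec = EnsembleSpec(n_models=200, p_mean=18.0, p_sd=5.0,
                        chi_mean=-160.0, chi_sd=8.0, seed=11)
    summary = conformer_distribution(generate_ensemble(dup, spec)).table
    # wrapped-median sampling error ~ 1.25*sd/sqrt(n) ~ 0.44 deg; allow 3x
    assert np.max(np.abs(summary["P_median"] - 18.0)) < 1.5
    assert np.max(np.abs(summary["chi_median"] + 160.0)) < 2.5


def test_ensemble_determinism_and_mirror_shift():
    dup = build_duplex("GC", A_FORM)
    spec = EnsembleSpec(n_models=20, p_sd=6.0, chi_sd=6.0, seed=4)
    e1 = generate_ensemble(dup, spec)
    e2 = generate_ensemble(dup, spec)
    assert all(np.array_equal(a.coords(), b.coords()) for a, b in zip(e1, e2))
    mirrored = ModelEnsemble(members=[mirror_structure(m) for m in e1])
    t1 = conformer_distribution(e1).table
    t2 = conformer_distribution(mirrored).table
    dP = (t2["P_median"].to_numpy() - t1["P_median"].to_numpy() - 180.0) % 360.0
    assert np.max(np.minimum(dP, 360.0 - dP)) < 1e-6
    assert np.max(np.abs(t2["chi_median"].to_numpy()
                         + t1["chi_median"].to_numpy())) < 1e-6


def test_infeasible_ring_closure_names_the_residue():
    dup = build_duplex("GC", A_FORM)
    spec = EnsembleSpec(n_models=1, vmax=120.0, seed=1)
    with pytest.raises(GenerationError, match="G1"):
        generate_ensemble(dup, spec)
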