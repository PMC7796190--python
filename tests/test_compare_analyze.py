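"""Superposition with reflection handling, RMSD machinery and circular
ensemble statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from mirrorhh._geom import rotation_about_axis
from mirrorhh.chirality import mirror_structure
from mirrorhh.compare_analyze import (
    circular_median,
    circular_quartiles,
    circular_summary,
    conformer_distribution,
    kabsch_superpose,
    region_rmsd_series,
    rmsd_selection,
    torsion_difference_profile,
)
from mirrorhh.structure_io import ModelEnsemble
from mirrorhh.synthetic import A_FORM, EnsembleSpec, build_duplex, generate_ensemble, perturb


def _chiral_points(rng, n=12):
    pts = rng.normal(size=(n, 3))
    return pts


def test_kabsch_identity(rng):
    pts = _chiral_points(rng)
    fit = kabsch_superpose(pts, pts)
    assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(fit.rotation, np.eye(3), atol=1e-9)
    assert fit.proper


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_kabsch_recovers_random_rigid_transform(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(10, 3))
    R = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 360))
    t = rng.normal(size=3)
    moved = pts @ R.T + t
    fit = kabsch_superpose(pts, moved)
    assert fit.rmsd < 1e-9
    assert fit.proper


def test_kabsch_agrees_with_scipy_align_vectors(rng):
    """Independent oracle: scipy's proper-rotation Procrustes."""
    P = _chiral_points(rng)
    Q = _chiral_points(rng)
    fit = kabsch_superpose(P, Q, allow_reflection=False)
    rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    assert np.allclose(fit.rotation, rot.as_matrix(), atol=1e-8)


def test_kabsch_reflection_handling(rng):
    """Enantiomers superpose exactly only when reflection is allowed."""
    pts = _chiral_points(rng)
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    allowed = kabsch_superpose(pts, mirrored, allow_reflection=True)
    proper = kabsch_superpose(pts, mirrored, allow_reflection=False)
    assert allowed.rmsd < 1e-9 and not allowed.proper
    assert proper.rmsd > 0.1 and proper.proper


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_reflection_equals_min_over_mirror_branch(seed):
    """kabsch(P,Q,reflect) == min(kabsch(P,Q), kabsch(mirror P, Q))."""
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(8, 3))
    Q = rng.normal(size=(8, 3))
    best = kabsch_superpose(P, Q, allow_reflection=True).rmsd
    branch = min(kabsch_superpose(P, Q).rmsd,
                 kabsch_superpose(P * np.array([1.0, 1.0, -1.0]), Q).rmsd)
    assert best == pytest.approx(branch, abs=1e-9)


def test_kabsch_errors_and_warnings(rng):
    with pytest.raises(ValueError, match="matching"):
        kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))
    line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
    with pytest.warns(UserWarning, match="collinear"):
        kabsch_superpose(line, line + 1.0)


def test_rmsd_selection_basics(scaffold):
    assert rmsd_selection(scaffold, scaffold)[0] == pytest.approx(0.0, abs=1e-12)
    rmsd, n = rmsd_selection(scaffold, perturb(scaffold, 0.05, 1), selection="S",
                             superpose=False)
    assert n == 289  # the substrate heavy-atom count
    r1 = rmsd_selection(scaffold, perturb(scaffold, 0.1, seed=9), superpose=False)
    r2 = rmsd_selection(scaffold, perturb(scaffold, 0.1, seed=9), superpose=False)
    assert r1 == r2  # bitwise reproducible


def test_rmsd_selection_mismatch_lists_offenders(a_duplex):
    broken = a_duplex.copy()
    del broken.chains[0].residues[0].atoms["O2'"]
    with pytest.raises(ValueError, match="O2'"):
        rmsd_selection(a_duplex, broken)


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=20, deadline=None)
def test_rmsd_is_a_metric_on_fixed_correspondence(seed):
    rng = np.random.default_rng(seed)
    A, B, C = (rng.normal(size=(7, 3)) for _ in range(3))

    def d(x, y):
        return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))

    assert d(A, B) == pytest.approx(d(B, A))
    assert d(A, C) <= d(A, B) + d(B, C) + 1e-12


def test_region_series_zero_for_identical_and_translated_frames(a_duplex):
    frames = [a_duplex.copy() for _ in range(3)]
    shifted = a_duplex.copy()
    shifted.set_all_coords(shifted.coords() + np.array([3.0, -2.0, 1.0]))
    frames.append(shifted)
    series = region_rmsd_series(ModelEnsemble(members=frames), {"all": None})
    assert np.max(series["rmsd"].to_numpy()) < 1e-9


def test_region_series_scales_with_noise(a_duplex):
    sigma = 0.1
    frames = [a_duplex.copy()] + [perturb(a_duplex, sigma, seed=s)
                                  for s in range(1, 7)]
    series = region_rmsd_series(ModelEnsemble(members=frames), {"all": None})
    vals = series[series["frame"] > 0]["rmsd"].to_numpy()
    # superposition removes ~6 dof; mean stays close to sigma*sqrt(3)
    assert abs(float(np.mean(vals)) - sigma * np.sqrt(3)) < 0.25 * sigma * np.sqrt(3)


def test_region_series_empty_region_raises(a_duplex):
    with pytest.raises(ValueError, match="empty"):
        region_rmsd_series(ModelEnsemble(members=[a_duplex.copy()]),
                           {"none": []})


def test_conformer_distribution_alternating_pucker():
    """Alternating N/S means produce alternating S fractions 0/1."""
    dup = build_duplex("GCGC", A_FORM)
    n_res = sum(len(c) for c in dup.chains)
    means = [18.0 if i % 2 == 0 else 162.0 for i in range(n_res)]
    ens = generate_ensemble(dup, EnsembleSpec(n_models=10, p_mean=means,
                                              p_sd=4.0, seed=3))
    table = conformer_distribution(ens).table
    assert np.allclose(table["frac_S"].to_numpy()[::2], 0.0)
    assert np.allclose(table["frac_S"].to_numpy()[1::2], 1.0)


def test_torsion_difference_profile(a_duplex):
    same = torsion_difference_profile(a_duplex, a_duplex)
    num = same[[c for c in same.columns if c.startswith("d_")]].to_numpy(float)
    assert np.nanmax(np.abs(num)) == 0.0
    mirrored = mirror_structure(a_duplex)
    direct = torsion_difference_profile(a_duplex, mirrored)
    # a vs mirror(a): every defined delta is 2*theta mod 360
    from mirrorhh.conformation import complex_records, records_to_frame
    ref = records_to_frame(complex_records(a_duplex))
    d_chi = direct["d_chi"].to_numpy(float)
    expected = ((2.0 * ref["chi"].to_numpy(float) + 180.0) % 360.0) - 180.0
    assert np.nanmax(np.abs(d_chi - expected)) < 1e-9
    re_mirrored = torsion_difference_profile(a_duplex,
                                             mirror_structure(mirrored))
    num2 = re_mirrored[[c for c in re_mirrored.columns
                        if c.startswith("d_")]].to_numpy(float)
    assert np.nanmax(np.abs(num2)) == 0.0


def test_torsion_difference_topology_mismatch(a_duplex, b_duplex):
    small = build_duplex("GA", A_FORM)
    with pytest.raises(ValueError, match="topology"):
        torsion_difference_profile(a_duplex, small)


def test_circular_summary_symmetry_report(a_duplex):
    mirrored = mirror_structure(a_duplex)
    table, symmetry = circular_summary([("DD", a_duplex), ("LL", mirrored)])
    assert len(table) == 2 * sum(len(c) for c in a_duplex.chains)
    assert symmetry["DD vs LL"] < 1e-9  # full mirror symmetry


def test_circular_median_handles_wraparound():
    angles = np.array([358.0, 2.0, 6.0, 354.0])
    med = circular_median(angles)
    assert min(abs(med - 0.0), abs(med - 360.0), abs(med - 358.0),
               abs(med - 2.0)) <= 4.0
    q1, med2, q3 = circular_quartiles(angles)
    rel = lambda a: ((a - med2 + 180.0) % 360.0) - 180.0
    assert rel(q1) <= 0.0 <= rel(q3)
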