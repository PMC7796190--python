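"""Mirror operation, chiral-centre signs and D/L classification."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from mirrorhh import templates
from mirrorhh._geom import place_by_two_angles
from mirrorhh.chirality import (
    chiral_sign,
    classify_residue_chirality,
    mirror_structure,
    validate_chirality,
)
from mirrorhh.structure_io import NucleotideResidue
from mirrorhh.synthetic import build_duplex


def test_mirror_negates_z_only(a_duplex):
    mirrored = mirror_structure(a_duplex)
    a = a_duplex.coords()
    b = mirrored.coords()
    assert np.array_equal(a[:, :2], b[:, :2])
    assert np.array_equal(a[:, 2], -b[:, 2])


def test_mirror_involution_is_exact(a_duplex):
    twice = mirror_structure(mirror_structure(a_duplex))
    assert np.array_equal(twice.coords(), a_duplex.coords())


def test_mirror_preserves_all_pairwise_distances_exactly(a_duplex):
    assert np.max(np.abs(pdist(a_duplex.coords())
                         - pdist(mirror_structure(a_duplex).coords()))) == 0.0


def test_chiral_sign_unit_examples():
    o = np.zeros(3)
    assert chiral_sign(o, [1, 0, 0], [0, 1, 0], [0, 0, 1]) == pytest.approx(1.0)
    assert chiral_sign(o, [1, 0, 0], [0, 1, 0], [0, 0, -1]) == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="degenerate"):
        chiral_sign(o, o, [0, 1, 0], [0, 0, 1])


def test_chiral_sign_flips_under_mirror_with_magnitude_preserved(a_duplex):
    from mirrorhh.chirality import residue_center_signs
    mirrored = mirror_structure(a_duplex)
    for ra, rb in zip(a_duplex.residues(), mirrored.residues()):
        va = residue_center_signs(ra)
        vb = residue_center_signs(rb)
        for c in va:
            assert vb[c] == pytest.approx(-va[c], abs=1e-9)


def test_template_residues_classify_D_and_mirrors_L(a_duplex):
    labels = {classify_residue_chirality(r) for r in a_duplex.residues()}
    assert labels == {"D"}
    labels_m = {classify_residue_chirality(r)
                for r in mirror_structure(a_duplex).residues()}
    assert labels_m == {"L"}


def test_every_builtin_template_matches_its_reference_signs():
    for code in templates.RNA_CODES:
        tpl = templates.get_template(code)
        res = NucleotideResidue.from_coords(1, code, dict(tpl.coords))
        assert classify_residue_chirality(res) == "D"


def test_single_flipped_center_is_invalid(a_duplex):
    res = a_duplex.chains[0].residues[1].copy()
    # re-place O2' on the opposite face of the C1'-C2'-C3' plane
    flipped = place_by_two_angles(res["C2'"], res["C1'"], res["C3'"],
                                  templates.O2P_BOND, *templates.O2P_ANGLES,
                                  branch=-templates._d_branch_signs()["O2'"])
    res.set_coords({"O2'": flipped})
    assert classify_residue_chirality(res) == "invalid"


def test_missing_center_atom_is_incomplete_residue_error(a_duplex):
    res = a_duplex.chains[0].residues[1].copy()
    del res.atoms["O2'"]
    with pytest.raises(ValueError, match="incomplete"):
        classify_residue_chirality(res)


def test_validate_chirality_clean_duplex(a_duplex):
    report = validate_chirality(a_duplex)
    assert report.verdict == "all-D"
    assert report.n_violations == 0


def test_validate_chirality_mixed_verdict(hetero_ld):
    report = validate_chirality(hetero_ld)
    assert report.verdict == "mixed"
    s_labels = {v for k, v in report.labels.items() if k.startswith("S/")}
    r_labels = {v for k, v in report.labels.items() if k.startswith("R/")}
    assert s_labels == {"L"} and r_labels == {"D"}


def test_validate_chirality_flags_stretched_bond():
    dup = build_duplex("GC")
    res = dup.chains[0].residues[0]
    # stretch the glycosidic bond by 0.2 A (beyond the 0.1 A tolerance)
    n = res["N9"]
    c1 = res["C1'"]
    direction = (n - c1) / np.linalg.norm(n - c1)
    shift = 0.2 * direction
    for name in res.base_atom_names():
        res.atoms[name].position = res[name] + shift
    report = validate_chirality(dup)
    assert any("C1'-N9" in v for v in report.bond_violations)


def test_report_json_serializable(a_duplex):
    report = validate_chirality(a_duplex)
    import json
    payload = json.loads(report.to_json())
    assert payload["verdict"] == "all-D"
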