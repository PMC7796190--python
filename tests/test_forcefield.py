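"""Parameter parsing, enantiomerization sign rules and the torsion-energy
mirror-invariance oracle."""

import io

import numpy as np
import pytest

from mirrorhh import forcefield as ff
from mirrorhh.chirality import mirror_structure
from mirrorhh.structure_io import NucleotideResidue, RNAChain, StructureComplex
from mirrorhh.synthetic import A_FORM, build_duplex

SAMPLE = """L-RNA test parameters
DIHE
CT-OS-CT-CT   1    1.10    30.7    3
OS-CT-CT-OH   1    0.50   180.0    2
IMPROPER
X-X-N2-H     1.10   180.0    2
"""


def test_parse_sizes_and_round_trip():
    pset = ff.parse_parameters(io.StringIO(SAMPLE))
    assert (len(pset.torsions), len(pset.impropers)) == (2, 1)
    buf = io.StringIO()
    ff.write_parameters(pset, buf)
    buf.seek(0)
    again = ff.parse_parameters(buf)
    assert again.torsions == pset.torsions
    assert again.impropers == pset.impropers


def test_missing_section_headers_is_a_parse_error():
    with pytest.raises(ff.ParameterParseError, match="section"):
        ff.parse_parameters(io.StringIO("just a title line\n"))


def test_malformed_numeric_field_reports_line_number():
    bad = "title\nDIHE\nCT-OS-CT-CT  1  nope  30.7  3\n"
    with pytest.raises(ff.ParameterParseError, match="line 3"):
        ff.parse_parameters(io.StringIO(bad))


def test_enantiomerize_sign_rules():
    pset = ff.parse_parameters(io.StringIO(SAMPLE))
    ent = ff.enantiomerize(pset)
    assert ent.provenance == "L"
    assert ent.torsions[0].phase == pytest.approx(329.3)   # 30.7 -> -30.7 mod 360
    assert ent.torsions[1].phase == pytest.approx(180.0)   # fixed point
    assert ent.impropers[0].k == pytest.approx(-1.1)       # sign flip
    assert ent.torsions[0].k == pset.torsions[0].k
    assert ent.torsions[0].periodicity == pset.torsions[0].periodicity


def test_enantiomerize_is_an_involution():
    pset = ff.parse_parameters(io.StringIO(SAMPLE))
    pset.impropers.append(ff.ImproperTerm(("A", "B", "C", "D"), 2.0, 0, 35.0))
    back = ff.enantiomerize(ff.enantiomerize(pset))
    assert back.torsions == pset.torsions
    assert back.impropers == pset.impropers
    assert back.provenance == pset.provenance


def _four_atom_complex(phi_deg: float) -> StructureComplex:
    """A single fake residue whose a1-a2-a3-a4 torsion equals phi."""
    from mirrorhh._geom import place_by_zmatrix
    p1 = np.array([0.0, 1.0, 0.0])
    p2 = np.zeros(3)
    p3 = np.array([1.5, 0.0, 0.0])
    p4 = place_by_zmatrix(p1, p2, p3, 1.5, 109.0, phi_deg)
    res = NucleotideResidue.from_coords(1, "A", {
        "a1": p1, "a2": p2, "a3": p3, "a4": p4})
    return StructureComplex([RNAChain("X", [res])])


QUAD = ((("X", 1, "a1"), ("X", 1, "a2"), ("X", 1, "a3"), ("X", 1, "a4")),)


@pytest.mark.parametrize("phi,expected", [(180.0, 0.0), (0.0, 2.0)])
def test_single_term_energy(phi, expected):
    term = ff.TorsionTerm(("c1", "c2", "c3", "c4"), 1.0, 1, 0.0)
    pset = ff.ParameterSet(torsions=[term])
    e = ff.torsion_energy(_four_atom_complex(phi), pset, {QUAD[0]: term})
    assert e == pytest.approx(expected, abs=1e-9)


def test_unassigned_term_raises():
    term = ff.TorsionTerm(("c1", "c2", "c3", "c4"), 1.0, 1, 0.0)
    stray = ff.TorsionTerm(("zz", "zz", "zz", "zz"), 1.0, 2, 10.0)
    pset = ff.ParameterSet(torsions=[term])
    with pytest.raises(ValueError, match="assignment error"):
        ff.torsion_energy(_four_atom_complex(10.0), pset, {QUAD[0]: stray})


def _full_backbone_assignment(dup):
    """Assign one torsion term (and one harmonic chirality improper) to every
    sugar torsion quadruple of the duplex."""
    t_ring = ff.TorsionTerm(("CS", "CS", "CS", "OS"), 1.4, 3, 30.7)
    t_gly = ff.TorsionTerm(("OS", "CS", "NN", "CN"), 0.9, 2, 75.0)
    imp = ff.ImproperTerm(("CS", "OS", "CS", "NN"), 2.3, 0, 118.2)
    pset = ff.ParameterSet(torsions=[t_ring, t_gly], impropers=[imp])
    assign = {}
    for chain in dup.chains:
        for res in chain.residues:
            cid = chain.chain_id
            i = res.index
            assign[((cid, i, "C1'"), (cid, i, "C2'"), (cid, i, "C3'"),
                    (cid, i, "C4'"))] = t_ring
            n9 = "N9" if res.code in "AG" else "N1"
            cc = "C4" if res.code in "AG" else "C2"
            assign[((cid, i, "O4'"), (cid, i, "C1'"), (cid, i, n9),
                    (cid, i, cc))] = [t_gly, imp]
    return pset, assign


def test_mirror_energy_invariance():
    """E(mirror X, enantiomerized params) == E(X, params) to 1e-9."""
    dup = build_duplex("GACU", A_FORM)
    pset, assign = _full_backbone_assignment(dup)
    e_d = ff.torsion_energy(dup, pset, assign)
    e_l = ff.torsion_energy(mirror_structure(dup), ff.enantiomerize(pset), assign)
    assert e_l == pytest.approx(e_d, rel=1e-9, abs=1e-9)


def test_d_parameters_on_mirrored_structure_are_not_invariant():
    """With phases outside {0, 180} the unmodified D set does not reproduce
    the energy on the mirror image -- the reason L parameters exist."""
    dup = build_duplex("GACU", A_FORM)
    pset, assign = _full_backbone_assignment(dup)
    e_d = ff.torsion_energy(dup, pset, assign)
    e_bad = ff.torsion_energy(mirror_structure(dup), pset, assign)
    assert abs(e_d - e_bad) > 1e-3
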