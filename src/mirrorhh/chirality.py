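"""Mirror transformations and D/L chirality assessment.

The mirror operation is the paper-of-record operation for building L-RNA
from D-RNA models: negate every atomic z coordinate.  It is an exact
involution, preserves all pairwise distances, and flips the sign of every
torsion angle and chiral-centre volume.

A residue is D when all four sugar stereocentres (C1'-C4') have substituent
signed volumes matching the template reference, L when all four are
opposite, and invalid otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .structure_io import Atom3D, NucleotideResidue, StructureComplex, ModelEnsemble
from .templates import (
    CHIRAL_CENTERS,
    GLYCOSIDIC_N,
    d_reference_signs,
    get_template,
)
from ._geom import angle_deg

__all__ = [
    "mirror_structure",
    "chiral_sign",
    "classify_residue_chirality",
    "validate_chirality",
    "ChiralityReport",
]

#: MAXIT-like leniency for covalent geometry violations
BOND_TOLERANCE = 0.1    # angstrom
ANGLE_TOLERANCE = 10.0  # degrees


def mirror_structure(complex_: StructureComplex) -> StructureComplex:
    """Reflect through the z=0 plane: (x, y, z) -> (x, y, -z).

    Chirality labels are recomputed (D residues become L and vice versa).
    Applying the operation twice restores the input exactly.
    """
    out = complex_.copy()
    for _, _, atom in out.atom_records():
        atom.position = atom.position * np.array([1.0, 1.0, -1.0])
    for res in out.residues():
        try:
            res.chirality = classify_residue_chirality(res)
        except ValueError:
            res.chirality = "unknown"
    return out


def mirror_ensemble(ensemble: ModelEnsemble) -> ModelEnsemble:
    return ModelEnsemble(members=[mirror_structure(m) for m in ensemble.members])


def chiral_sign(center: Atom3D | np.ndarray, s1, s2, s3) -> float:
    """Signed volume (angstrom^3): (s1-c) . ((s2-c) x (s3-c)).

    Flips sign under reflection; magnitude is reflection-invariant.
    """
    def pos(a):
        return a.position if isinstance(a, Atom3D) else np.asarray(a, float)

    c = pos(center)
    v1, v2, v3 = pos(s1) - c, pos(s2) - c, pos(s3) - c
    if min(np.linalg.norm(v) for v in (v1, v2, v3)) < 1e-6:
        raise ValueError("degenerate geometry: coincident atoms in chiral centre")
    return float(np.dot(v1, np.cross(v2, v3)))


def residue_center_signs(res: NucleotideResidue) -> dict[str, float]:
    """Signed volumes at the four sugar stereocentres of one residue."""
    nname = GLYCOSIDIC_N[res.code]
    out = {}
    for center, subs in CHIRAL_CENTERS:
        names = [nname if s == "N" else s for s in subs]
        missing = [n for n in (center, *names) if n not in res]
        if missing:
            raise ValueError(
                f"incomplete residue {res.code}{res.index}: missing {missing}")
        out[center] = chiral_sign(res[center], *(res[n] for n in names))
    return out


def classify_residue_chirality(res: NucleotideResidue) -> str:
    """D / L / invalid from the four sugar stereocentres."""
    signs = residue_center_signs(res)
    ref = d_reference_signs(res.code)
    matches = [np.sign(signs[c]) == ref[c] for c in signs]
    if all(matches):
        return "D"
    if not any(matches):
        return "L"
    return "invalid"


@dataclass
class ChiralityReport:
    """Per-residue chirality labels, centre volumes, covalent-geometry
    violations, and the overall verdict."""

    labels: dict[str, str]                 # "chain/index" -> {D, L, invalid}
    center_volumes: dict[str, dict[str, float]]
    bond_violations: list[str] = field(default_factory=list)
    angle_violations: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        values = set(self.labels.values())
        if "invalid" in values or not values:
            return "invalid"
        if values == {"D"}:
            return "all-D"
        if values == {"L"}:
            return "all-L"
        return "mixed"

    @property
    def n_violations(self) -> int:
        return len(self.bond_violations) + len(self.angle_violations)

    def to_json(self, **kwargs) -> str:
        payload = asdict(self)
        payload["verdict"] = self.verdict
        return json.dumps(payload, indent=2, **kwargs)


def _template_bond_lengths(code: str) -> dict[tuple[str, str], float]:
    from .restraints import residue_bond_list  # local import avoids a cycle
    tpl = get_template(code)
    out = {}
    for a, b in residue_bond_list(code):
        out[(a, b)] = float(np.linalg.norm(tpl.coords[a] - tpl.coords[b]))
    return out


def _template_angles(code: str) -> dict[tuple[str, str, str], float]:
    from .restraints import residue_angle_list
    tpl = get_template(code)
    return {
        (a, b, c): angle_deg(tpl.coords[a], tpl.coords[b], tpl.coords[c])
        for a, b, c in residue_angle_list(code)
    }


def validate_chirality(complex_: StructureComplex) -> ChiralityReport:
    """MAXIT-style validation: covalent bond/angle geometry against the ideal
    templates (tolerance 0.1 angstrom / 10 degrees) plus chirality labels.

    The verdict is "mixed" when chains disagree -- the heterochiral case.
    """
    labels: dict[str, str] = {}
    volumes: dict[str, dict[str, float]] = {}
    bond_v: list[str] = []
    angle_v: list[str] = []
    for chain in complex_.chains:
        for res in chain.residues:
            key = f"{chain.chain_id}/{res.index}"
            try:
                volumes[key] = residue_center_signs(res)
                labels[key] = classify_residue_chirality(res)
            except ValueError:
                labels[key] = "invalid"
                volumes[key] = {}
            for (a, b), ideal in _template_bond_lengths(res.code).items():
                if a in res and b in res:
                    d = float(np.linalg.norm(res[a] - res[b]))
                    if abs(d - ideal) > BOND_TOLERANCE:
                        bond_v.append(f"{key} {a}-{b}: {d:.3f} vs {ideal:.3f}")
            for (a, b, c), ideal in _template_angles(res.code).items():
                if a in res and b in res and c in res:
                    ang = angle_deg(res[a], res[b], res[c])
                    if abs(ang - ideal) > ANGLE_TOLERANCE:
                        angle_v.append(f"{key} {a}-{b}-{c}: {ang:.1f} vs {ideal:.1f}")
            res.chirality = labels[key]
    return ChiralityReport(labels=labels, center_volumes=volumes,
                           bond_violations=bond_v, angle_violations=angle_v)
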