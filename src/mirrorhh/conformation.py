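"""Per-residue conformational descriptors: backbone torsions alpha..zeta,
glycosidic chi with syn/anti classification, furanose ring torsions,
Altona-Sundaralingam pseudorotation (P, vmax) with pucker classes, and
phosphorus-phosphorus distances.

Wrap conventions: torsions in (-180, 180], pseudorotation phase in [0, 360).
A torsion whose atoms are missing (chain termini) is reported as absent
(None / NaN), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geom import dihedral_deg, wrap180, wrap360
from .structure_io import NucleotideResidue, RNAChain, StructureComplex
from .templates import CHI_BASE_ATOM, GLYCOSIDIC_N, PURINES

__all__ = [
    "dihedral",
    "backbone_torsions",
    "glycosidic_chi",
    "classify_syn_anti",
    "pseudorotation",
    "classify_pucker",
    "phosphate_distances",
    "ConformationRecord",
    "conformation_record",
    "chain_records",
    "complex_records",
    "records_to_frame",
]

#: below this pseudorotation amplitude (deg) the ring is effectively flat
#: and the phase is reported as undefined
AMPLITUDE_FLOOR = 5.0

#: the five endocyclic torsions, nu0..nu4
NU_QUADS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)

#: the 20 envelope/twist conformers of the pseudorotation wheel, one per
#: 18-degree bin centred at P = 0, 18, 36, ...; envelopes carry the familiar
#: endo/exo names, twists the two flanking ring atoms
_PUCKER_WHEEL = (
    "3T2", "C3'-endo", "3T4", "C4'-exo", "0T4",
    "O4'-endo", "0T1", "C1'-exo", "2T1", "C2'-endo",
    "2T3", "C3'-exo", "4T3", "C4'-endo", "4T0",
    "O4'-exo", "1T0", "C1'-endo", "1T2", "C2'-exo",
)


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, (-180, 180], IUPAC signs."""
    return dihedral_deg(p1, p2, p3, p4)


def _get(res: NucleotideResidue | None, name: str):
    if res is None or name not in res:
        return None
    return res[name]


def backbone_torsions(chain: RNAChain) -> list[dict[str, float | None]]:
    """alpha..zeta per residue; angles undefined at termini are None."""
    out = []
    residues = chain.residues
    for i, res in enumerate(residues):
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        quads = {
            "alpha": (_get(prev, "O3'"), _get(res, "P"), _get(res, "O5'"), _get(res, "C5'")),
            "beta": (_get(res, "P"), _get(res, "O5'"), _get(res, "C5'"), _get(res, "C4'")),
            "gamma": (_get(res, "O5'"), _get(res, "C5'"), _get(res, "C4'"), _get(res, "C3'")),
            "delta": (_get(res, "C5'"), _get(res, "C4'"), _get(res, "C3'"), _get(res, "O3'")),
            "epsilon": (_get(res, "C4'"), _get(res, "C3'"), _get(res, "O3'"), _get(nxt, "P")),
            "zeta": (_get(res, "C3'"), _get(res, "O3'"), _get(nxt, "P"), _get(nxt, "O5'")),
        }
        row = {}
        for name, pts in quads.items():
            row[name] = None if any(p is None for p in pts) else dihedral_deg(*pts)
        out.append(row)
    return out


def glycosidic_chi(res: NucleotideResidue) -> float:
    """chi: O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for pyrimidines."""
    n = GLYCOSIDIC_N[res.code]
    c = CHI_BASE_ATOM[res.code]
    for name in ("O4'", "C1'", n, c):
        if name not in res:
            raise ValueError(
                f"incomplete residue {res.code}{res.index}: missing {name} for chi")
    return dihedral_deg(res["O4'"], res["C1'"], res[n], res[c])


def classify_syn_anti(chi: float) -> str:
    """anti iff |chi| >= 90 after wrapping to (-180, 180]; boundary -> anti."""
    if not np.isfinite(chi):
        raise ValueError("chi must be finite")
    return "anti" if abs(float(wrap180(chi))) >= 90.0 else "syn"


def ring_nu_torsions(res: NucleotideResidue) -> np.ndarray:
    for quad in NU_QUADS:
        for name in quad:
            if name not in res:
                raise ValueError(
                    f"incomplete residue {res.code}{res.index}: missing ring atom {name}")
    return np.array([dihedral_deg(*(res[n] for n in quad)) for quad in NU_QUADS])


def pseudorotation_from_nus(nus: np.ndarray) -> tuple[float | None, float]:
    """(P, vmax) from the five ring torsions.

    P = atan2((nu4+nu1)-(nu3+nu0), 2*nu2*(sin36+sin72)); the atan2 on the
    signed denominator realises the usual "add 180 deg when nu2 < 0" rule.
    vmax = nu2/cos(P) >= 0.  P is None below the amplitude floor.
    """
    nus = np.asarray(nus, dtype=float)
    num = (nus[4] + nus[1]) - (nus[3] + nus[0])
    den = 2.0 * nus[2] * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))
    if abs(num) < 1e-12 and abs(den) < 1e-12:
        return None, 0.0
    P = float(np.degrees(np.arctan2(num, den)))
    vmax = float(nus[2] / np.cos(np.radians(P))) if abs(np.cos(np.radians(P))) > 1e-12 \
        else float(num / (2.0 * np.sin(np.radians(P)) * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))))
    if vmax < AMPLITUDE_FLOOR:
        return None, vmax
    return float(wrap360(P)), vmax


def pseudorotation(res: NucleotideResidue) -> tuple[float | None, float]:
    """Pseudorotation phase and amplitude of the sugar ring, degrees."""
    return pseudorotation_from_nus(ring_nu_torsions(res))


def classify_pucker(P: float | None) -> tuple[str, str]:
    """(N/S/other class, 18-degree-bin conformer name) for phase P."""
    if P is None or not np.isfinite(P):
        raise ValueError("cannot classify an undefined pseudorotation phase")
    P = float(wrap360(P))
    if P >= 315.0 or P < 45.0:
        klass = "N"
    elif 135.0 <= P < 225.0:
        klass = "S"
    else:
        klass = "other"
    sector = int(np.floor((P + 9.0) / 18.0)) % 20
    return klass, _PUCKER_WHEEL[sector]


def phosphate_distances(chain: RNAChain) -> list[float]:
    """Consecutive intra-strand P-P distances, 5'->3'."""
    ps = [r["P"] for r in chain.residues if "P" in r]
    return [float(np.linalg.norm(b - a)) for a, b in zip(ps, ps[1:])]


@dataclass
class ConformationRecord:
    """All conformational descriptors of one residue (degrees)."""

    chain_id: str
    index: int
    code: str
    alpha: float | None
    beta: float | None
    gamma: float | None
    delta: float | None
    epsilon: float | None
    zeta: float | None
    chi: float | None
    nus: tuple[float, ...] | None
    P: float | None
    vmax: float | None
    pucker_class: str | None
    pucker_name: str | None
    glycosidic_class: str | None


def conformation_record(chain: RNAChain, res: NucleotideResidue,
                        backbone_row: dict[str, float | None]) -> ConformationRecord:
    try:
        chi = glycosidic_chi(res)
        glyc = classify_syn_anti(chi)
    except ValueError:
        chi, glyc = None, None
    try:
        nus = ring_nu_torsions(res)
        P, vmax = pseudorotation_from_nus(nus)
        nus_t = tuple(float(x) for x in nus)
    except ValueError:
        nus_t, P, vmax = None, None, None
    if P is not None:
        klass, name = classify_pucker(P)
    else:
        klass, name = None, None
    return ConformationRecord(
        chain_id=chain.chain_id, index=res.index, code=res.code,
        alpha=backbone_row["alpha"], beta=backbone_row["beta"],
        gamma=backbone_row["gamma"], delta=backbone_row["delta"],
        epsilon=backbone_row["epsilon"], zeta=backbone_row["zeta"],
        chi=chi, nus=nus_t, P=P, vmax=vmax,
        pucker_class=klass, pucker_name=name, glycosidic_class=glyc)


def chain_records(chain: RNAChain) -> list[ConformationRecord]:
    rows = backbone_torsions(chain)
    return [conformation_record(chain, res, row)
            for res, row in zip(chain.residues, rows)]


def complex_records(complex_: StructureComplex) -> list[ConformationRecord]:
    out = []
    for chain in complex_.chains:
        out.extend(chain_records(chain))
    return out


def records_to_frame(records: list[ConformationRecord],
                     model: int | None = None) -> pd.DataFrame:
    """Tidy table (one row per residue), the substrate of all reports."""
    rows = []
    for r in records:
        row = {
            "chain": r.chain_id, "residue": r.index, "code": r.code,
            "alpha": r.alpha, "beta": r.beta, "gamma": r.gamma,
            "delta": r.delta, "epsilon": r.epsilon, "zeta": r.zeta,
            "chi": r.chi, "P": r.P, "vmax": r.vmax,
            "pucker_class": r.pucker_class, "pucker_name": r.pucker_name,
            "glycosidic_class": r.glycosidic_class,
        }
        if model is not None:
            row["model"] = model
        rows.append(row)
    return pd.DataFrame(rows)
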