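"""Superposition, RMSD and ensemble statistics for homo/heterochiral
structure comparisons.

The central subtlety is chirality: a least-squares superposition that admits
an improper (reflection) component will overlay a structure onto its mirror
image with zero RMSD, which silently erases exactly the property under
study.  `kabsch_superpose` therefore exposes reflection handling explicitly,
and heterochiral comparisons default to proper rotations only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geom import wrap180, wrap360
from .conformation import (
    chain_records,
    classify_pucker,
    classify_syn_anti,
    complex_records,
    records_to_frame,
)
from .structure_io import ModelEnsemble, StructureComplex

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "rmsd_selection",
    "region_rmsd_series",
    "ConformerSummary",
    "conformer_distribution",
    "torsion_difference_profile",
    "circular_summary",
    "resolve_selection",
    "BACKBONE_RIBOSE_ATOMS",
]

#: ribose-phosphate backbone selection (O2' excluded by default; pass your
#: own atom set to include it)
BACKBONE_RIBOSE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, orthogonal
    translation: np.ndarray   # 3-vector
    rmsd: float
    n_atoms: int

    @property
    def proper(self) -> bool:
        return bool(np.linalg.det(self.rotation) > 0)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_superpose(P: np.ndarray, Q: np.ndarray,
                     allow_reflection: bool = False) -> SuperpositionResult:
    """Least-squares rigid superposition of P onto Q (correspondence by
    order).

    With ``allow_reflection=False`` the transform is restricted to proper
    rotations (chirality-preserving).  With ``True`` an improper transform is
    used when it lowers the RMSD -- enantiomers then superpose exactly.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must have matching (n, 3) shapes, "
                         f"got {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise ValueError("need at least 3 corresponding points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-9 * max(s[0], 1.0):
        warnings.warn("near-degenerate (collinear) point set; superposition "
                      "is ill-conditioned", stacklevel=2)
    det = np.sign(np.linalg.det(Vt.T @ U.T))
    if allow_reflection:
        d = 1.0 if det >= 0 else -1.0
        # improper transform allowed: keep whichever branch lowers RMSD;
        # the optimal branch always uses the unmodified SVD solution
        D = np.eye(3)
    else:
        D = np.diag([1.0, 1.0, det])
    R = Vt.T @ D @ U.T
    moved = P0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q0) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=cq - R @ cp,
                               rmsd=rmsd, n_atoms=len(P))


def resolve_selection(complex_: StructureComplex, selection=None,
                      atom_filter=None) -> list[tuple[str, int, str]]:
    """Expand a selection into (chain_id, residue_index, atom_name) keys.

    `selection`: None (everything), a chain id, or an iterable of
    (chain_id, residue_index) pairs.  `atom_filter`: iterable of atom names
    to keep (e.g. the ribose-phosphate backbone).
    """
    keep_res = None
    if selection is not None:
        if isinstance(selection, str):
            keep_res = {(selection, r.index) for r in complex_.chain(selection)}
        else:
            keep_res = {(c, int(i)) for c, i in selection}
    keep_atoms = set(atom_filter) if atom_filter is not None else None
    keys = []
    for ch, res, atom in complex_.atom_records():
        if keep_res is not None and (ch.chain_id, res.index) not in keep_res:
            continue
        if keep_atoms is not None and atom.name not in keep_atoms:
            continue
        keys.append((ch.chain_id, res.index, atom.name))
    return keys


def _coords_for_keys(complex_: StructureComplex,
                     keys: list[tuple[str, int, str]]) -> np.ndarray:
    out = np.empty((len(keys), 3))
    for k, (cid, ridx, aname) in enumerate(keys):
        res = complex_.chain(cid).residue(ridx)
        if aname not in res:
            raise ValueError(f"selection error: {cid}/{ridx} lacks atom {aname}")
        out[k] = res[aname]
    return out


def rmsd_selection(a: StructureComplex, b: StructureComplex, selection=None,
                   atom_filter=None, superpose: bool = True,
                   allow_reflection: bool = False) -> tuple[float, int]:
    """RMSD over a selection, optionally after superposition on it.

    Returns (rmsd, atom count used).  Atom lists must match name-by-name;
    mismatches are reported explicitly.
    """
    keys_a = resolve_selection(a, selection, atom_filter)
    keys_b = resolve_selection(b, selection, atom_filter)
    if keys_a != keys_b:
        only_a = [k for k in keys_a if k not in set(keys_b)][:5]
        only_b = [k for k in keys_b if k not in set(keys_a)][:5]
        raise ValueError(f"selection mismatch; first offenders: "
                         f"a-only {only_a}, b-only {only_b}")
    if not keys_a:
        raise ValueError("empty selection")
    pa = _coords_for_keys(a, keys_a)
    pb = _coords_for_keys(b, keys_b)
    if superpose:
        fit = kabsch_superpose(pa, pb, allow_reflection=allow_reflection)
        return fit.rmsd, fit.n_atoms
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1)))), len(pa)


def region_rmsd_series(ensemble: ModelEnsemble, regions: dict[str, object],
                       reference: int = 0, atom_filter=BACKBONE_RIBOSE_ATOMS,
                       allow_reflection: bool = False) -> pd.DataFrame:
    """Per-frame, per-region RMSD to a reference frame, each region
    superposed on itself (ribose-phosphate backbone atoms by default)."""
    if len(ensemble) < 1:
        raise ValueError("empty ensemble")
    ref = ensemble[reference]
    rows = []
    for name, sel in regions.items():
        keys = resolve_selection(ref, sel, atom_filter)
        if not keys:
            raise ValueError(f"selection error: region {name!r} is empty")
        ref_coords = _coords_for_keys(ref, keys)
        for f, frame in enumerate(ensemble):
            pc = _coords_for_keys(frame, keys)
            fit = kabsch_superpose(pc, ref_coords, allow_reflection=allow_reflection)
            rows.append({"frame": f, "region": name, "rmsd": fit.rmsd,
                         "n_atoms": fit.n_atoms})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def circular_median(angles_deg: np.ndarray, period: float = 360.0) -> float:
    """Wrapped median: the sample angle minimising the mean circular
    deviation; exact ties (e.g. the two central values of an even-sized
    sample) resolve to the circular mean of the tied candidates, which keeps
    the median equivariant under mirroring (negation)."""
    a = np.mod(np.asarray(angles_deg, dtype=float), period)
    if a.size == 0:
        raise ValueError("no angles")
    half = period / 2.0
    devs = []
    for cand in a:
        d = np.abs((a - cand + half) % period - half)
        devs.append(np.mean(d))
    devs = np.asarray(devs)
    best = np.min(devs)
    winners = a[devs <= best + 1e-12]
    if winners.size == 1:
        return float(winners[0])
    rad = np.radians(winners * (360.0 / period))
    mean = np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    return float(np.mod(mean * (period / 360.0), period))


def circular_quartiles(angles_deg: np.ndarray, period: float = 360.0
                       ) -> tuple[float, float, float]:
    """(q1, median, q3) on the circle, measured around the wrapped median."""
    med = circular_median(angles_deg, period)
    half = period / 2.0
    rel = (np.asarray(angles_deg, float) - med + half) % period - half
    q1, q3 = np.percentile(rel, [25, 75])
    return (float((med + q1) % period), med, float((med + q3) % period))


@dataclass
class ConformerSummary:
    """Per-residue circular statistics of P and chi over an ensemble."""

    table: pd.DataFrame  # chain, residue, code, medians/quartiles, fractions
    excluded: list[tuple[str, int]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def conformer_distribution(ensemble: ModelEnsemble) -> ConformerSummary:
    """Circular median/quartiles of P and chi per residue, plus S-type and
    syn fractions -- the table behind violin-style ensemble plots."""
    if len(ensemble) < 1:
        raise ValueError("empty ensemble")
    per_frame = [records_to_frame(complex_records(m), model=i)
                 for i, m in enumerate(ensemble)]
    df = pd.concat(per_frame, ignore_index=True)
    rows, excluded = [], []
    for (chain, residue, code), grp in df.groupby(["chain", "residue", "code"],
                                                  sort=False):
        ps = grp["P"].dropna().to_numpy()
        chis = grp["chi"].dropna().to_numpy()
        if ps.size == 0:
            excluded.append((chain, residue))
            continue
        p_q1, p_med, p_q3 = circular_quartiles(ps, 360.0)
        row = {
            "chain": chain, "residue": residue, "code": code,
            "P_median": p_med, "P_q1": p_q1, "P_q3": p_q3,
            "frac_S": float(np.mean([classify_pucker(p)[0] == "S" for p in ps])),
            "n": int(len(grp)),
        }
        if chis.size:
            c_q1, c_med, c_q3 = circular_quartiles(wrap180(chis) % 360.0, 360.0)
            row.update({
                "chi_median": float(wrap180(c_med)),
                "chi_q1": float(wrap180(c_q1)),
                "chi_q3": float(wrap180(c_q3)),
                "frac_syn": float(np.mean([classify_syn_anti(c) == "syn"
                                           for c in chis])),
            })
        rows.append(row)
    return ConformerSummary(table=pd.DataFrame(rows), excluded=excluded)


def torsion_difference_profile(a: StructureComplex,
                               b: StructureComplex) -> pd.DataFrame:
    """Wrapped per-residue angle differences a-b for alpha..zeta, chi and P."""
    if a.topology_key() != b.topology_key():
        raise ValueError("comparison error: topology mismatch")
    fa = records_to_frame(complex_records(a))
    fb = records_to_frame(complex_records(b))
    out = fa[["chain", "residue", "code"]].copy()
    for col in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi", "P"):
        va, vb = fa[col].to_numpy(dtype=float), fb[col].to_numpy(dtype=float)
        diff = wrap180(va - vb)
        diff[np.isnan(va) | np.isnan(vb)] = np.nan
        out[f"d_{col}"] = diff
    return out


def circular_summary(labelled: list[tuple[str, StructureComplex]]
                     ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Tidy (complex, chain, residue, P, chi) table for polar plots, plus a
    mirror-symmetry report.

    For every pair of labels the report stores the largest deviation from
    the ideal mirror relation P' = P+180, chi' = -chi; exact enantiomer
    pairs score ~0 (full symmetry).
    """
    rows = []
    for label, cx in labelled:
        df = records_to_frame(complex_records(cx))
        df.insert(0, "complex", label)
        rows.append(df[["complex", "chain", "residue", "code", "P", "chi"]])
    table = pd.concat(rows, ignore_index=True)

    symmetry: dict[str, float] = {}
    labels = [lab for lab, _ in labelled]
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            ta = table[table["complex"] == la]
            tb = table[table["complex"] == lb]
            if len(ta) != len(tb):
                continue
            dp = wrap180(tb["P"].to_numpy(float)
                         - (ta["P"].to_numpy(float) + 180.0))
            dc = wrap180(tb["chi"].to_numpy(float) + ta["chi"].to_numpy(float))
            dev = np.nanmax(np.abs(np.concatenate([dp, dc])))
            symmetry[f"{la} vs {lb}"] = float(dev)
    return table, symmetry
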