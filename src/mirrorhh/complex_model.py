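"""Hammerhead-specific model logic.

Covers: locating the GUC|N cleavage motif, deriving the three-helix pairing
topology from sequence complementarity, template-based heavy-atom
accounting, geometric Watson-Crick pair detection, construction of
heterochiral complexes by per-residue enantiomerization with base-frame
anchoring, and Watson-Crick-restrained refinement.

Chain conventions follow the scaffold builder: "R" = ribozyme, "S" =
substrate, residues numbered 1..n, 5'->3'.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import templates
from ._geom import rotation_about_axis
from .restraints import build_restraints
from .structure_io import NucleotideResidue, RNAChain, StructureComplex
from .templates import WC_COMPLEMENT, WC_HBONDS

__all__ = [
    "BasePair",
    "PairingMap",
    "RefinementSettings",
    "TopologyError",
    "find_cleavage_sites",
    "hammerhead_pairing",
    "count_heavy_atoms",
    "detect_wc_pairs_3d",
    "build_heterochiral",
    "restrained_refine",
]


class TopologyError(ValueError):
    """The sequences do not support a hammerhead pairing topology."""


@dataclass
class BasePair:
    res_a: tuple[str, int]
    res_b: tuple[str, int]
    pair_type: str = "other"            # {G-C, A-U, other}
    helix: str | None = None            # {H1, H2, H3, None}
    chirality_class: str | None = None  # {homochiral, heterochiral, None}
    hbond_distances: tuple[float, ...] = ()
    planarity_angle: float | None = None

    def residues(self):
        return (self.res_a, self.res_b)


def _pair_type(code_a: str, code_b: str) -> str:
    pair = frozenset((code_a, code_b))
    if pair == frozenset(("G", "C")):
        return "G-C"
    if pair == frozenset(("A", "U")):
        return "A-U"
    return "other"


@dataclass
class PairingMap:
    """Helix-labelled base-pair list plus unpaired residues and the cleavage
    site, all as (chain_id, 1-based index) references."""

    pairs: list[BasePair] = field(default_factory=list)
    unpaired: set[tuple[str, int]] = field(default_factory=set)
    cleavage_site: tuple[str, int] | None = None

    def __post_init__(self):
        seen: set[tuple[str, int]] = set()
        for p in self.pairs:
            for ref in p.residues():
                if ref in seen:
                    raise ValueError(f"residue {ref} appears in two pairs")
                seen.add(ref)

    def helix_pairs(self, helix: str) -> list[BasePair]:
        return [p for p in self.pairs if p.helix == helix]

    def paired_residues(self) -> set[tuple[str, int]]:
        out = set()
        for p in self.pairs:
            out.update(p.residues())
        return out

    def to_json(self) -> str:
        return json.dumps({
            "pairs": [{
                "a": list(p.res_a), "b": list(p.res_b), "type": p.pair_type,
                "helix": p.helix} for p in self.pairs],
            "unpaired": sorted(list(u) for u in self.unpaired),
            "cleavage_site": list(self.cleavage_site) if self.cleavage_site else None,
        }, indent=2)

    def to_dot_bracket(self, ribozyme_len: int, substrate_len: int) -> str:
        """Two-chain dot-bracket (ribozyme & substrate, '&'-separated);
        intramolecular pairs use (), inter-chain pairs []."""
        r = ["."] * ribozyme_len
        s = ["."] * substrate_len
        for p in self.pairs:
            (ca, ia), (cb, ib) = p.res_a, p.res_b
            if ca == cb == "R":
                r[min(ia, ib) - 1] = "("
                r[max(ia, ib) - 1] = ")"
            else:
                ri = ia if ca == "R" else ib
                si = ia if ca == "S" else ib
                r[ri - 1] = "["
                s[si - 1] = "]"
        return "".join(r) + "&" + "".join(s)


def find_cleavage_sites(seq: str) -> list[int]:
    """1-based positions of the C in each GUC motif followed by at least one
    nucleotide (cleavage occurs 3' of that C)."""
    seq = seq.upper()
    out = []
    for i in range(3, len(seq)):            # i is the 1-based position of C
        if seq[i - 3:i] == "GUC" and i < len(seq):
            out.append(i)
    return out


def hammerhead_pairing(ribozyme_seq: str, substrate_seq: str) -> PairingMap:
    """Derive the hammerhead pairing topology from the two sequences.

    H1: substrate 3' flank vs the ribozyme 5' arm; H3: substrate 5' flank vs
    the ribozyme 3' arm (both maximal antiparallel complementary runs
    anchored at the strand ends).  H2: the maximal intramolecular stem
    closing a 4-nt loop within the ribozyme core.  Everything else is
    unpaired core.
    """
    rz = ribozyme_seq.upper()
    sub = substrate_seq.upper()
    sites = find_cleavage_sites(sub)
    if len(sites) != 1:
        raise TopologyError(
            f"substrate must contain exactly one GUC|N site, found {len(sites)}")
    site = sites[0]

    pairs: list[BasePair] = []

    # helix 1: substrate 3' end paired into the ribozyme 5' arm
    tail = sub[site:]  # residues site+1 .. n  (5'->3')
    run1 = 0
    while (run1 < len(tail)
           and run1 < len(rz)
           and WC_COMPLEMENT[sub[len(sub) - 1 - run1]] == rz[run1]):
        run1 += 1
    if run1 < 2:
        mism = [f"substrate {len(sub) - k} ({sub[len(sub)-1-k]}) vs ribozyme "
                f"{k + 1} ({rz[k]})" for k in range(min(3, len(tail)))
                if WC_COMPLEMENT[sub[len(sub)-1-k]] != rz[k]]
        raise TopologyError("helix 1 arm not complementary: " + "; ".join(mism))
    run1 = min(run1, len(tail))  # never pair across the cleavage site
    for k in range(run1):
        s_idx, r_idx = len(sub) - k, k + 1
        pairs.append(BasePair(("S", s_idx), ("R", r_idx),
                              _pair_type(sub[s_idx - 1], rz[r_idx - 1]), "H1"))

    # helix 3: substrate 5' flank vs the ribozyme 3' arm, anchored at the
    # residue 5' of the scissile phosphate (the cleavage-site C itself stays
    # unpaired in the hammerhead core)
    def run_at(j0: int) -> int:
        run = 0
        while True:
            s_idx, r_idx = site - 1 - run, j0 + run
            if s_idx < 1 or r_idx > len(rz):
                break
            if WC_COMPLEMENT[sub[s_idx - 1]] != rz[r_idx - 1]:
                break
            run += 1
        return run

    best = (None, 0)
    for j0 in range(run1 + 1, len(rz) + 1):   # 1-based rz start of the run
        run = run_at(j0)
        # among equal-length runs prefer the one reaching the rz 3' terminus
        if run > best[1] or (run == best[1] and run > 0 and j0 + run - 1 == len(rz)):
            best = (j0, run)
    j0, run3 = best
    if run3 < 2:
        raise TopologyError("helix 3 arm not complementary to the substrate 5' flank")
    for k in range(run3):
        s_idx = site - 1 - k
        r_idx = j0 + k
        pairs.append(BasePair(("S", s_idx), ("R", r_idx),
                              _pair_type(sub[s_idx - 1], rz[r_idx - 1]), "H3"))

    # helix 2: maximal intramolecular stem closing a 4-nt loop in the core
    core_lo, core_hi = run1 + 1, j0 - 1   # 1-based inclusive bounds
    best2 = (None, 0)
    loop_len = 4
    for s0 in range(core_lo, core_hi + 1):
        for stem in range(1, (core_hi - core_lo + 1) // 2 + 1):
            # stem: s0..s0+stem-1 pairs (s0+stem+loop+stem-1) .. down
            last = s0 + 2 * stem + loop_len - 1
            if last > core_hi:
                break
            ok = all(
                WC_COMPLEMENT[rz[s0 - 1 + t]] == rz[last - 1 - t]
                for t in range(stem))
            if ok and stem > best2[1]:
                best2 = (s0, stem)
    if best2[0] is None:
        raise TopologyError("no intramolecular stem (helix 2) found in the core")
    s0, stem = best2
    for t in range(stem):
        a, b = s0 + t, s0 + 2 * stem + loop_len - 1 - t
        pairs.append(BasePair(("R", a), ("R", b),
                              _pair_type(rz[a - 1], rz[b - 1]), "H2"))

    paired = set()
    for p in pairs:
        paired.update(p.residues())
    unpaired = {("R", i) for i in range(1, len(rz) + 1) if ("R", i) not in paired}
    unpaired |= {("S", i) for i in range(1, len(sub) + 1) if ("S", i) not in paired}
    return PairingMap(pairs=pairs, unpaired=unpaired, cleavage_site=("S", site))


def count_heavy_atoms(selection, five_prime_phosphate: bool = False) -> int:
    """Template-based heavy-atom count.

    `selection` may be a sequence string, an RNAChain, a StructureComplex,
    or an iterable of those.  For sequences the 5'-terminus policy defaults
    to a free 5'-OH (no terminal phosphate); chains/complexes are counted by
    their residues' own composition policy.
    """
    if isinstance(selection, str):
        seq = selection.upper()
        return sum(templates.heavy_atom_count(c, five_prime_phosphate or i > 0)
                   for i, c in enumerate(seq))
    if isinstance(selection, RNAChain):
        return sum(templates.heavy_atom_count(r.code, r.five_prime_phosphate)
                   for r in selection.residues)
    if isinstance(selection, StructureComplex):
        return sum(count_heavy_atoms(c) for c in selection.chains)
    try:
        return sum(count_heavy_atoms(item) for item in selection)
    except TypeError:
        raise TypeError(f"cannot resolve selection {selection!r}")


def _base_normal(res: NucleotideResidue) -> np.ndarray:
    n = res[templates.GLYCOSIDIC_N[res.code]]
    v1 = res[templates.CHI_BASE_ATOM[res.code]] - n
    v2 = res[templates.OTHER_N_NEIGHBOUR[res.code]] - n
    nrm = np.cross(v1, v2)
    return nrm / np.linalg.norm(nrm)


def detect_wc_pairs_3d(complex_: StructureComplex, dmax: float = 3.5,
                       planarity_max: float = 35.0) -> list[BasePair]:
    """Geometric Watson-Crick pair detection.

    A pair is reported when every type-specific donor-acceptor distance is
    <= dmax and the angle between the base normals is <= planarity_max
    (after folding to [0, 90]).  Pairs are labelled homo-/heterochiral from
    the residues' chirality labels.
    """
    entries = []
    for chain in complex_.chains:
        for res in chain.residues:
            entries.append((chain.chain_id, res))
    found = []
    for i in range(len(entries)):
        cid_a, res_a = entries[i]
        for j in range(i + 1, len(entries)):
            cid_b, res_b = entries[j]
            contacts = WC_HBONDS.get((res_a.code, res_b.code))
            if contacts is None:
                continue
            try:
                dists = tuple(
                    float(np.linalg.norm(res_a[a] - res_b[b]))
                    for a, b in contacts)
            except KeyError:
                continue
            if max(dists) > dmax:
                continue
            na, nb = _base_normal(res_a), _base_normal(res_b)
            cosang = abs(float(np.dot(na, nb)))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang > planarity_max:
                continue
            # reject stacked (vertically offset) geometries that satisfy the
            # distance cutoffs edge-on: the partner base must sit in-plane
            ca = np.mean([res_a[n] for n in res_a.base_atom_names()], axis=0)
            cb = np.mean([res_b[n] for n in res_b.base_atom_names()], axis=0)
            if abs(float(np.dot(cb - ca, na))) > 2.0:
                continue
            chir = None
            if res_a.chirality in ("D", "L") and res_b.chirality in ("D", "L"):
                chir = ("homochiral" if res_a.chirality == res_b.chirality
                        else "heterochiral")
            found.append(BasePair(
                res_a=(cid_a, res_a.index), res_b=(cid_b, res_b.index),
                pair_type=_pair_type(res_a.code, res_b.code),
                chirality_class=chir, hbond_distances=dists,
                planarity_angle=ang))
    return found


def annotate_helices(pairs: list[BasePair], pairing: PairingMap) -> list[BasePair]:
    """Copy helix labels from a pairing map onto detected pairs."""
    lookup = {}
    for p in pairing.pairs:
        lookup[frozenset(p.residues())] = p.helix
    for p in pairs:
        p.helix = lookup.get(frozenset(p.residues()))
    return pairs


@dataclass
class RefinementSettings:
    """Parameters of the restrained gradient-descent refinement."""

    steps: int = 1000
    step_size: float = 1e-4          # initial step along -grad, angstrom^2/kcal
    k_bond: float = 300.0            # kcal/mol/A^2
    k_angle: float = 50.0            # kcal/mol/rad^2
    k_hbond: float = 10.0            # kcal/mol/A^2, target ~2.9 A
    k_plane: float = 5.0             # kcal/mol (dimensionless normal term)
    k_anchor: float = 0.5            # kcal/mol/A^2 on anchored base atoms
    k_chiral: float = 5.0            # kcal/mol/A^6, sugar stereocentre volumes
    hbond_target: float | None = None  # None -> per-contact ideal (~2.9 A)
    energy_tolerance: float = 1e-10

    def __post_init__(self):
        for name in ("k_bond", "k_angle", "k_hbond", "k_plane", "k_anchor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def restrained_refine(complex_: StructureComplex, pairing: PairingMap | None,
                      settings: RefinementSettings | None = None,
                      anchor_atoms=None) -> tuple[StructureComplex, list[float]]:
    """Gradient descent with backtracking on the harmonic restraint energy
    (bonds + angles toward template ideals, WC hydrogen bonds, base-pair
    planarity, optional position anchors).

    Returns the refined copy and the (non-increasing) energy trace.
    Deterministic; raises on non-finite energy.
    """
    settings = settings or RefinementSettings()
    out = complex_.copy()
    rset = build_restraints(
        out, pairing, k_bond=settings.k_bond, k_angle=settings.k_angle,
        k_hbond=settings.k_hbond, k_plane=settings.k_plane,
        hbond_target=settings.hbond_target, anchor_atoms=anchor_atoms,
        k_anchor=settings.k_anchor, k_chiral=settings.k_chiral)
    x = out.coords().reshape(-1)
    energy, grad = rset.energy_and_gradient(x)
    if not np.isfinite(energy):
        raise RuntimeError("refinement error: non-finite restraint energy")
    trace = [energy]
    lam = settings.step_size
    for _ in range(settings.steps):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < 1e-12:
            break
        accepted = False
        for _try in range(40):
            x_new = x - lam * grad
            e_new, g_new = rset.energy_and_gradient(x_new)
            if np.isfinite(e_new) and e_new <= energy:
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            break
        delta = energy - e_new
        x, energy, grad = x_new, e_new, g_new
        trace.append(energy)
        lam = min(lam * 1.25, 1e-2)
        if delta < settings.energy_tolerance:
            break
    out.set_all_coords(x.reshape(-1, 3))
    from .synthetic import _label_chirality
    _label_chirality(out)
    return out, trace


def build_heterochiral(complex_: StructureComplex, strand: str,
                       pairing: PairingMap | None = None,
                       settings: RefinementSettings | None = None,
                       refine: bool = True) -> StructureComplex:
    """Enantiomerize one strand in place: mirror each of its residues, then
    rigidly re-superpose (proper rotation) each mirrored residue so its base
    heavy atoms coincide with the pre-mirror base position (base-frame
    anchoring), and finally re-join the backbone by restrained refinement.

    Planar bases are achiral, so the anchoring leaves every base essentially
    where Watson-Crick pairing put it; only the sugar-phosphate backbone
    changes hand.  Applying the operation to the same strand twice restores
    the all-homochiral complex (at the label level).
    """
    if pairing is None:
        raise ValueError("precondition error: build_heterochiral needs the "
                         "complex's PairingMap")
    from .chirality import classify_residue_chirality
    from .compare_analyze import kabsch_superpose

    out = complex_.copy()
    chain = out.chain(strand)
    mirror = np.array([1.0, 1.0, -1.0])
    for res in chain.residues:
        base_names = res.base_atom_names()
        base_before = res.coords(base_names)
        mirrored = {n: res[n] * mirror for n in res.atom_names()}
        src = np.array([mirrored[n] for n in base_names])
        fit = kabsch_superpose(src, base_before, allow_reflection=False)
        res.set_coords({n: fit.apply(p[None, :])[0] for n, p in mirrored.items()})
        res.chirality = classify_residue_chirality(res)

    if refine:
        settings = settings or RefinementSettings()
        anchors = []
        hetero_residues = set()
        for p in pairing.pairs:
            (ca, ia), (cb, ib) = p.res_a, p.res_b
            if ca != cb:  # inter-strand pair: heterochiral after the flip
                hetero_residues.add((ca, ia))
                hetero_residues.add((cb, ib))
        for cid, idx in sorted(hetero_residues):
            res = out.chain(cid).residue(idx)
            for name in res.base_atom_names():
                anchors.append((cid, idx, name, res[name].copy()))
        out, _ = restrained_refine(out, pairing, settings, anchor_atoms=anchors)
    return out
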