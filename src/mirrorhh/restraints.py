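"""Harmonic restraint energy for Watson-Crick-restrained refinement.

Terms: bonds and bond angles toward ideal-template values, Watson-Crick
donor-acceptor distances toward the ideal-pair values (~2.9 angstrom),
base-plane coplanarity for paired bases, and optional harmonic position
anchors.  Bonds, angles and non-bonded terms of a force field are achiral;
these restraints therefore apply identically to D and L residues.

All gradients are analytic; the refinement driver in
:mod:`mirrorhh.complex_model` only needs `energy_and_gradient`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import templates
from ._geom import angle_deg
from .structure_io import StructureComplex

__all__ = ["RestraintSet", "build_restraints", "residue_bond_list", "residue_angle_list"]


@lru_cache(maxsize=None)
def _base_bonds(code: str) -> tuple[tuple[str, str], ...]:
    """Covalent bonds among base heavy atoms, from the CCD connectivity."""
    from biotite.structure.info import residue as ccd_residue

    ccd = ccd_residue(code)
    names = list(ccd.atom_name)
    base = set(templates.BASE_ATOMS[code])
    out = []
    for i, j, _ in ccd.bonds.as_array():
        a, b = names[i], names[j]
        if a in base and b in base:
            out.append((a, b))
    return tuple(sorted(out))


_SUGAR_BONDS = (
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"),
    ("C4'", "C3'"), ("C4'", "O4'"), ("C3'", "O3'"), ("C3'", "C2'"),
    ("C2'", "O2'"), ("C2'", "C1'"), ("C1'", "O4'"),
)


@lru_cache(maxsize=None)
def residue_bond_list(code: str) -> tuple[tuple[str, str], ...]:
    """Intra-residue heavy-atom bonds (5'-phosphate variant; subset applies
    to 5'-OH residues)."""
    glyco = (("C1'", templates.GLYCOSIDIC_N[code]),)
    return _SUGAR_BONDS + glyco + _base_bonds(code)


@lru_cache(maxsize=None)
def residue_angle_list(code: str) -> tuple[tuple[str, str, str], ...]:
    """All bonded angle triples a-b-c implied by the residue bond graph."""
    adj: dict[str, set[str]] = {}
    for a, b in residue_bond_list(code):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    out = []
    for b, nbrs in sorted(adj.items()):
        ns = sorted(nbrs)
        for i in range(len(ns)):
            for j in range(i + 1, len(ns)):
                out.append((ns[i], b, ns[j]))
    return tuple(out)


@lru_cache(maxsize=None)
def _template_distance(code: str, a: str, b: str) -> float:
    tpl = templates.get_template(code)
    return float(np.linalg.norm(tpl.coords[a] - tpl.coords[b]))


@lru_cache(maxsize=None)
def _template_angle(code: str, a: str, b: str, c: str) -> float:
    tpl = templates.get_template(code)
    return angle_deg(tpl.coords[a], tpl.coords[b], tpl.coords[c])


@dataclass
class RestraintSet:
    """Indexed harmonic restraints over a flat coordinate array."""

    n_atoms: int
    bond_idx: np.ndarray = field(default=None)      # (nb, 2)
    bond_ideal: np.ndarray = field(default=None)    # (nb,)
    bond_k: np.ndarray = field(default=None)
    angle_idx: np.ndarray = field(default=None)     # (na, 3)
    angle_ideal_rad: np.ndarray = field(default=None)
    angle_k: np.ndarray = field(default=None)
    plane_triples: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    plane_k: float = 0.0
    anchor_idx: np.ndarray = field(default=None)
    anchor_pos: np.ndarray = field(default=None)
    anchor_k: float = 0.0
    # chirality-enforcing improper-volume restraints on the sugar
    # stereocentres: E = k*(V - V0)^2 with V the substituent scalar triple
    # product; V0's sign encodes the residue's hand (D vs L)
    chiral_idx: np.ndarray = field(default=None)    # (nc, 4): centre, s1..s3
    chiral_target: np.ndarray = field(default=None)
    chiral_k: float = 0.0

    def energy_and_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = coords.reshape(-1, 3)
        grad = np.zeros_like(x)
        energy = 0.0

        if self.bond_idx is not None and len(self.bond_idx):
            i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
            d = x[i] - x[j]
            r = np.linalg.norm(d, axis=1)
            dev = r - self.bond_ideal
            energy += float(np.sum(self.bond_k * dev ** 2))
            f = (2.0 * self.bond_k * dev / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(grad, i, f)
            np.add.at(grad, j, -f)

        if self.angle_idx is not None and len(self.angle_idx):
            ia, ib, ic = (self.angle_idx[:, k] for k in range(3))
            u = x[ia] - x[ib]
            v = x[ic] - x[ib]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            cos_t = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
            theta = np.arccos(cos_t)
            dev = theta - self.angle_ideal_rad
            energy += float(np.sum(self.angle_k * dev ** 2))
            sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 1e-12))
            ga = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
            gc = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
            pref = (2.0 * self.angle_k * dev)[:, None]
            np.add.at(grad, ia, pref * ga)
            np.add.at(grad, ic, pref * gc)
            np.add.at(grad, ib, -pref * (ga + gc))

        if self.plane_triples and self.plane_k > 0.0:
            for t1, t2 in self.plane_triples:
                e, g = _plane_term(x, t1, t2, self.plane_k)
                energy += e
                grad += g

        if self.chiral_idx is not None and len(self.chiral_idx) and self.chiral_k > 0:
            c = x[self.chiral_idx[:, 0]]
            v1 = x[self.chiral_idx[:, 1]] - c
            v2 = x[self.chiral_idx[:, 2]] - c
            v3 = x[self.chiral_idx[:, 3]] - c
            cr23 = np.cross(v2, v3)
            V = np.sum(v1 * cr23, axis=1)
            dev = V - self.chiral_target
            energy += float(self.chiral_k * np.sum(dev ** 2))
            pref = (2.0 * self.chiral_k * dev)[:, None]
            g1 = pref * cr23
            g2 = pref * np.cross(v3, v1)
            g3 = pref * np.cross(v1, v2)
            np.add.at(grad, self.chiral_idx[:, 1], g1)
            np.add.at(grad, self.chiral_idx[:, 2], g2)
            np.add.at(grad, self.chiral_idx[:, 3], g3)
            np.add.at(grad, self.chiral_idx[:, 0], -(g1 + g2 + g3))

        if self.anchor_idx is not None and len(self.anchor_idx):
            d = x[self.anchor_idx] - self.anchor_pos
            energy += float(self.anchor_k * np.sum(d ** 2))
            np.add.at(grad, self.anchor_idx, 2.0 * self.anchor_k * d)

        return energy, grad.reshape(-1)


def _plane_term(x: np.ndarray, t1: np.ndarray, t2: np.ndarray,
                k: float) -> tuple[float, np.ndarray]:
    """Coplanarity term E = k*(1 - (n1.n2)^2) on two 3-atom plane normals.

    Minimal (zero, with zero gradient) when the planes are parallel or
    antiparallel, so it penalises only genuine buckling between the bases.
    """
    def normal(t):
        p1, p2, p3 = x[t[0]], x[t[1]], x[t[2]]
        u = p2 - p1
        v = p3 - p1
        n = np.cross(u, v)
        return n, u, v

    n1, u1, v1 = normal(t1)
    n2, u2, v2 = normal(t2)
    l1 = np.linalg.norm(n1)
    l2 = np.linalg.norm(n2)
    if l1 < 1e-9 or l2 < 1e-9:
        return 0.0, np.zeros_like(x)
    h1, h2 = n1 / l1, n2 / l2
    c = float(np.dot(h1, h2))
    energy = k * (1.0 - c * c)
    # dE/dn1 = -2kc * d(h1.h2)/dn1 = -2kc * (h2 - c*h1)/l1
    g_n1 = -2.0 * k * c * (h2 - c * h1) / l1
    g_n2 = -2.0 * k * c * (h1 - c * h2) / l2
    grad = np.zeros_like(x)
    for (t, g_n, u, v) in ((t1, g_n1, u1, v1), (t2, g_n2, u2, v2)):
        # n = u x v with u = p2-p1, v = p3-p1
        g_p2 = np.cross(v, g_n)
        g_p3 = np.cross(g_n, u)
        grad[t[1]] += g_p2
        grad[t[2]] += g_p3
        grad[t[0]] -= g_p2 + g_p3
    return energy, grad


@lru_cache(maxsize=None)
def _template_chiral_volume(code: str, center: str) -> float:
    """Signed substituent volume at a sugar stereocentre of the D template."""
    tpl = templates.get_template(code)
    nname = templates.GLYCOSIDIC_N[code]
    subs = dict(templates.CHIRAL_CENTERS)[center]
    names = [nname if s == "N" else s for s in subs]
    c = tpl.coords[center]
    v = [tpl.coords[s] - c for s in names]
    return float(np.dot(v[0], np.cross(v[1], v[2])))


def build_restraints(complex_: StructureComplex, pairing=None, *,
                     k_bond: float = 300.0, k_angle: float = 50.0,
                     k_hbond: float = 10.0, k_plane: float = 5.0,
                     hbond_target: float | None = None,
                     anchor_atoms=None, k_anchor: float = 0.5,
                     k_chiral: float = 5.0) -> RestraintSet:
    """Assemble the restraint set for a complex.

    `pairing` (a PairingMap or an iterable of BasePair) contributes the WC
    hydrogen-bond and planarity terms.  `hbond_target` of None means the
    per-contact ideal-pair distance (~2.9 angstrom).  `anchor_atoms` is an
    iterable of (chain_id, residue_index, atom_name, position) records.
    """
    index: dict[tuple[str, int, str], int] = {}
    for k, (ch, res, atom) in enumerate(complex_.atom_records()):
        index[(ch.chain_id, res.index, atom.name)] = k
    n_atoms = len(index)

    bond_idx, bond_ideal, bond_k = [], [], []
    angle_idx, angle_ideal, angle_k = [], [], []

    for chain in complex_.chains:
        for pos, res in enumerate(chain.residues):
            cid = chain.chain_id
            for a, b in residue_bond_list(res.code):
                if a in res and b in res:
                    bond_idx.append((index[(cid, res.index, a)], index[(cid, res.index, b)]))
                    bond_ideal.append(_template_distance(res.code, a, b))
                    bond_k.append(k_bond)
            for a, b, c in residue_angle_list(res.code):
                if a in res and b in res and c in res:
                    angle_idx.append(tuple(index[(cid, res.index, nm)] for nm in (a, b, c)))
                    angle_ideal.append(np.radians(_template_angle(res.code, a, b, c)))
                    angle_k.append(k_angle)
            if pos + 1 < len(chain.residues):
                nxt = chain.residues[pos + 1]
                if "O3'" in res and "P" in nxt:
                    i_o3 = index[(cid, res.index, "O3'")]
                    i_p = index[(cid, nxt.index, "P")]
                    bond_idx.append((i_o3, i_p))
                    bond_ideal.append(templates.O3_P_BOND)
                    bond_k.append(k_bond)
                    if "C3'" in res:
                        angle_idx.append((index[(cid, res.index, "C3'")], i_o3, i_p))
                        angle_ideal.append(np.radians(templates.C3_O3_P_ANGLE))
                        angle_k.append(k_angle)
                    for other, ideal in (("O5'", templates.O3_P_O5_ANGLE),
                                         ("OP1", templates.OP_ANGLE_O3),
                                         ("OP2", templates.OP_ANGLE_O3)):
                        if other in nxt:
                            angle_idx.append((i_o3, i_p, index[(cid, nxt.index, other)]))
                            angle_ideal.append(np.radians(ideal))
                            angle_k.append(k_angle)

    plane_triples = []
    if pairing is not None:
        pairs = getattr(pairing, "pairs", pairing)
        for pair in pairs:
            (ch_a, i_a), (ch_b, i_b) = pair.res_a, pair.res_b
            res_a = complex_.chain(ch_a).residue(i_a)
            res_b = complex_.chain(ch_b).residue(i_b)
            key = (res_a.code, res_b.code)
            contacts = templates.WC_HBONDS.get(key)
            if contacts is None:
                continue
            ideal = templates.pair_frame(res_a.code).hbond_distances() \
                if res_a.code in ("G", "A") else \
                templates.pair_frame(res_b.code).hbond_distances()
            for (a, b), d0 in zip(contacts, ideal):
                bond_idx.append((index[(ch_a, i_a, a)], index[(ch_b, i_b, b)]))
                bond_ideal.append(float(d0) if hbond_target is None else hbond_target)
                bond_k.append(k_hbond)
            t_a = _plane_triple(res_a, index, ch_a)
            t_b = _plane_triple(res_b, index, ch_b)
            plane_triples.append((t_a, t_b))

    # chirality-enforcing impropers: the target sign follows the residue's
    # current hand, so D and L strands are each held in their own geometry
    chiral_idx, chiral_target = [], []
    for chain in complex_.chains:
        for res in chain.residues:
            nname = templates.GLYCOSIDIC_N[res.code]
            for center, subs in templates.CHIRAL_CENTERS:
                names = [nname if s == "N" else s for s in subs]
                if center not in res or any(n not in res for n in names):
                    continue
                c = res[center]
                v = [res[n] - c for n in names]
                sign = np.sign(np.dot(v[0], np.cross(v[1], v[2]))) or 1.0
                chiral_idx.append(tuple(
                    index[(chain.chain_id, res.index, n)] for n in (center, *names)))
                chiral_target.append(
                    sign * abs(_template_chiral_volume(res.code, center)))

    anchor_idx, anchor_pos = [], []
    if anchor_atoms:
        for cid, ridx, aname, pos_ in anchor_atoms:
            anchor_idx.append(index[(cid, ridx, aname)])
            anchor_pos.append(np.asarray(pos_, float))

    return RestraintSet(
        n_atoms=n_atoms,
        bond_idx=np.array(bond_idx, dtype=int).reshape(-1, 2),
        bond_ideal=np.array(bond_ideal, dtype=float),
        bond_k=np.array(bond_k, dtype=float),
        angle_idx=np.array(angle_idx, dtype=int).reshape(-1, 3),
        angle_ideal_rad=np.array(angle_ideal, dtype=float),
        angle_k=np.array(angle_k, dtype=float),
        plane_triples=plane_triples,
        plane_k=k_plane,
        anchor_idx=np.array(anchor_idx, dtype=int) if anchor_idx else np.array([], dtype=int),
        anchor_pos=np.array(anchor_pos, dtype=float).reshape(-1, 3),
        anchor_k=k_anchor,
        chiral_idx=np.array(chiral_idx, dtype=int).reshape(-1, 4),
        chiral_target=np.array(chiral_target, dtype=float),
        chiral_k=k_chiral,
    )


def _plane_triple(res, index, cid) -> np.ndarray:
    n = templates.GLYCOSIDIC_N[res.code]
    trio = (n, templates.CHI_BASE_ATOM[res.code], templates.OTHER_N_NEIGHBOUR[res.code])
    return np.array([index[(cid, res.index, t)] for t in trio], dtype=int)
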