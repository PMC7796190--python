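"""Ideal ribonucleotide geometry: residue templates, the pseudorotation-driven
ribose builder, and ideal Watson-Crick pair frames.

The sugar/phosphate internal coordinates are pinned constants (standard
ribonucleotide geometry); base ring geometry is taken from the Chemical
Component Dictionary bundled with biotite and flattened onto its best-fit
plane.  Everything downstream (helix generation, restrained refinement,
heavy-atom accounting, chirality references) derives from the values in this
module, so all reported numbers are reproducible from here.

Conventions: heavy atoms only, PDB v3 atom names with ' as the prime
character, 1-based residue numbering 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from ._geom import (
    angle_deg,
    dihedral_deg,
    normalize,
    place_by_two_angles,
    place_by_zmatrix,
    rotation_about_axis,
    wrap180,
)

RNA_CODES = ("A", "C", "G", "U")

#: Base heavy atoms, in emission order (ring atoms first, as in PDB practice).
BASE_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

#: Sugar-phosphate heavy atoms with a 5'-phosphate (12) / with a free 5'-OH (9).
BACKBONE_ATOMS: tuple[str, ...] = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
)
PHOSPHATE_ATOMS: tuple[str, ...] = ("P", "OP1", "OP2")

PURINES = ("A", "G")
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}
#: second atom of the chi torsion on the base side
CHI_BASE_ATOM = {"A": "C4", "G": "C4", "C": "C2", "U": "C2"}
#: the other ring neighbour of the glycosidic nitrogen
OTHER_N_NEIGHBOUR = {"A": "C8", "G": "C8", "C": "C6", "U": "C6"}

#: Watson-Crick donor/acceptor heavy-atom contacts, keyed by (purine-side?) codes.
WC_HBONDS: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {
    ("G", "C"): (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),
    ("C", "G"): (("N4", "O6"), ("N3", "N1"), ("O2", "N2")),
    ("A", "U"): (("N6", "O4"), ("N1", "N3")),
    ("U", "A"): (("O4", "N6"), ("N3", "N1")),
}

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# ---------------------------------------------------------------------------
# Pinned internal coordinates (angstrom / degree).  Standard ribose geometry;
# the ring least-squares builder balances these against the requested ring
# torsions, so small deviations from the printed values are expected.
# ---------------------------------------------------------------------------

RING_ORDER = ("C4'", "O4'", "C1'", "C2'", "C3'")  # traversal used by the builder
RING_BONDS = {
    ("C4'", "O4'"): 1.453,
    ("O4'", "C1'"): 1.414,
    ("C1'", "C2'"): 1.528,
    ("C2'", "C3'"): 1.525,
    ("C3'", "C4'"): 1.524,
}
RING_ANGLES = {
    ("C3'", "C4'", "O4'"): 105.5,
    ("C4'", "O4'", "C1'"): 109.7,
    ("O4'", "C1'", "C2'"): 106.4,
    ("C1'", "C2'", "C3'"): 101.5,
    ("C2'", "C3'", "C4'"): 102.7,
}

#: nu torsions in Altona-Sundaralingam order; nu_j = vmax*cos(P + 144*j).
NU_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
)

# exocyclic substituents: name -> (bond length, (nb1, angle1), (nb2, angle2))
GLYCO_BOND = 1.471           # C1'-N9 / C1'-N1
GLYCO_ANGLES = (108.2, 113.2)  # O4'-C1'-N, C2'-C1'-N
O2P_BOND, O2P_ANGLES = 1.413, (110.6, 113.3)   # C1'-C2'-O2', C3'-C2'-O2'
O3P_BOND, O3P_ANGLES = 1.423, (110.6, 110.7)   # C4'-C3'-O3', C2'-C3'-O3'
C5P_BOND, C5P_ANGLES = 1.510, (115.5, 109.2)   # C3'-C4'-C5', O4'-C4'-C5'
O5P_BOND, O5P_ANGLE = 1.440, 110.2             # C4'-C5'-O5'
P_BOND, P_ANGLE = 1.593, 120.9                 # C5'-O5'-P
O3_P_BOND = 1.595                               # inter-residue O3'(i-1)-P(i)
C3_O3_P_ANGLE = 119.7                           # C3'-O3'-P(i+1)
O3_P_O5_ANGLE = 104.0                           # O3'(i-1)-P-O5'
OP_BOND = 1.485
OP_ANGLE_O5 = 108.1                             # O5'-P-OP1/OP2
OP_ANGLE_O3 = 107.4                             # O3'(prev)-P-OP1/OP2

#: canonical amplitude of the sugar pucker (degrees)
DEFAULT_VMAX = 38.0

#: ideal WC pair frame parameters: C1'-C1' span and lambda angle (both sides).
#: Solved once so that, with the flattened CCD bases, every canonical
#: donor-acceptor contact sits at 2.90 angstrom while both glycosidic bonds
#: keep their CCD orientation; shared by all pair types (exact isostericity).
C1C1_DISTANCE = 10.906
LAMBDA_DEG = 52.45
HBOND_TARGET = 2.90


def heavy_atom_names(code: str, five_prime_phosphate: bool = True) -> tuple[str, ...]:
    """Heavy-atom names of a residue in emission order."""
    if code not in RNA_CODES:
        raise ValueError(f"unknown residue code {code!r}")
    backbone = BACKBONE_ATOMS if five_prime_phosphate else BACKBONE_ATOMS[3:]
    return backbone + BASE_ATOMS[code]


def heavy_atom_count(code: str, five_prime_phosphate: bool = True) -> int:
    return len(heavy_atom_names(code, five_prime_phosphate))


# ---------------------------------------------------------------------------
# CCD base geometry
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def base_geometry(code: str) -> dict[str, np.ndarray]:
    """Rigid base heavy-atom coordinates from the CCD, flattened onto the
    best-fit plane (bases are treated as exactly planar throughout)."""
    from biotite.structure.info import residue as ccd_residue

    ccd = ccd_residue(code)
    names = BASE_ATOMS[code]
    coords = {}
    for name in names:
        sel = ccd.coord[ccd.atom_name == name]
        if len(sel) != 1:
            raise ValueError(f"CCD residue {code} lacks base atom {name}")
        coords[name] = np.asarray(sel[0], dtype=float)
    pts = np.array([coords[n] for n in names])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    flat = pts - np.outer((pts - centroid) @ normal, normal)
    return {n: flat[i] for i, n in enumerate(names)}


@lru_cache(maxsize=None)
def _ccd_n_internal(code: str) -> dict[str, float]:
    """Bond lengths / in-plane layout of the glycosidic nitrogen's base-side
    neighbours, measured on the flattened CCD base."""
    base = base_geometry(code)
    n = base[GLYCOSIDIC_N[code]]
    cchi = base[CHI_BASE_ATOM[code]]
    cother = base[OTHER_N_NEIGHBOUR[code]]
    return {
        "bond_chi": float(np.linalg.norm(cchi - n)),
        "bond_other": float(np.linalg.norm(cother - n)),
        "angle_chi_other": angle_deg(cchi, n, cother),
    }


# ---------------------------------------------------------------------------
# Ribose ring from (P, vmax)
# ---------------------------------------------------------------------------

def ring_torsions(P: float, vmax: float) -> np.ndarray:
    """The five endocyclic torsions nu0..nu4 implied by phase P and amplitude
    vmax (Altona-Sundaralingam)."""
    j = np.arange(5)
    return vmax * np.cos(np.radians(P + 144.0 * (j - 2)))


@lru_cache(maxsize=4096)
def _build_ring_cached(P_key: float, vmax_key: float) -> tuple[tuple[float, ...], ...]:
    coords = _build_ring(P_key, vmax_key)
    return tuple(tuple(row) for row in coords)


def build_ring(P: float, vmax: float = DEFAULT_VMAX) -> dict[str, np.ndarray]:
    """Five ring atoms (local frame) whose torsions realise the requested
    pseudorotation state.

    Bond lengths, bond angles and the five target torsions over-determine a
    closed five-ring, so a weighted least-squares polish balances them; the
    achieved phase matches the request to well under a degree for ordinary
    amplitudes.
    """
    key = (round(float(P) % 360.0, 9), round(float(vmax), 9))
    rows = _build_ring_cached(*key)
    return {name: np.array(rows[i]) for i, name in enumerate(RING_ORDER)}


def _build_ring(P: float, vmax: float) -> np.ndarray:
    nus = ring_torsions(P, vmax)
    # sequential seed: C4' at origin, O4' on +x, C1' in the xy plane, then
    # C2', C3' placed from nu0, nu1
    c4 = np.zeros(3)
    o4 = np.array([RING_BONDS[("C4'", "O4'")], 0.0, 0.0])
    ang = np.radians(RING_ANGLES[("C4'", "O4'", "C1'")])
    c1 = o4 + RING_BONDS[("O4'", "C1'")] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    c2 = place_by_zmatrix(c4, o4, c1, RING_BONDS[("C1'", "C2'")],
                          RING_ANGLES[("O4'", "C1'", "C2'")], nus[0])
    c3 = place_by_zmatrix(o4, c1, c2, RING_BONDS[("C2'", "C3'")],
                          RING_ANGLES[("C1'", "C2'", "C3'")], nus[1])
    x0 = np.concatenate([c4, o4, c1, c2, c3])

    idx = {n: i for i, n in enumerate(RING_ORDER)}
    bond_i = np.array([(idx[a], idx[b]) for (a, b) in RING_BONDS])
    bond_l = np.array(list(RING_BONDS.values()))
    ang_i = np.array([(idx[a], idx[b], idx[c]) for (a, b, c) in RING_ANGLES])
    ang_v = np.radians(np.array(list(RING_ANGLES.values())))
    nu_i = np.array([[idx[n] for n in quad] for quad in NU_ATOMS])
    nu_t = np.radians(nus)

    w_bond, w_angle, w_tor = 100.0, 10.0, 30.0

    def residuals(x: np.ndarray) -> np.ndarray:
        pts = x.reshape(5, 3)
        d = pts[bond_i[:, 0]] - pts[bond_i[:, 1]]
        r_bond = np.linalg.norm(d, axis=1) - bond_l
        u = pts[ang_i[:, 0]] - pts[ang_i[:, 1]]
        v = pts[ang_i[:, 2]] - pts[ang_i[:, 1]]
        cos_t = np.sum(u * v, axis=1) / (np.linalg.norm(u, axis=1)
                                         * np.linalg.norm(v, axis=1))
        r_ang = np.arccos(np.clip(cos_t, -1.0, 1.0)) - ang_v
        b1 = pts[nu_i[:, 1]] - pts[nu_i[:, 0]]
        b2 = pts[nu_i[:, 2]] - pts[nu_i[:, 1]]
        b3 = pts[nu_i[:, 3]] - pts[nu_i[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2h = b2 / np.linalg.norm(b2, axis=1)[:, None]
        y = np.sum(np.cross(n1, n2) * b2h, axis=1)
        xc = np.sum(n1 * n2, axis=1)
        tor = np.arctan2(y, xc)
        r_tor = np.arctan2(np.sin(tor - nu_t), np.cos(tor - nu_t))
        return np.concatenate([w_bond * r_bond, w_angle * r_ang, w_tor * r_tor])

    sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12, gtol=1e-12)
    pts = sol.x.reshape(5, 3)
    res = residuals(sol.x)
    closure = np.max(np.abs(res[:5])) / 100.0          # worst bond deviation, A
    angle_dev = np.degrees(np.max(np.abs(res[5:10])) / 10.0)
    torsion_dev = np.degrees(np.max(np.abs(res[10:])) / 30.0)
    if closure > 0.1 or torsion_dev > 15.0 or angle_dev > 20.0:
        raise ValueError(
            f"infeasible ring closure at P={P:.1f}, vmax={vmax:.1f} "
            f"(bond dev {closure:.2f} A, angle dev {angle_dev:.1f} deg, "
            f"torsion dev {torsion_dev:.1f} deg)")
    return pts


# ---------------------------------------------------------------------------
# Full nucleotide in a local frame
# ---------------------------------------------------------------------------

def _branch_sign(center, nb1, nb2, target) -> float:
    """Orientation (+1/-1) that puts `target` on its side of the nb1-center-nb2
    plane; used to reproduce the D configuration of the reference."""
    u = np.asarray(nb1, float) - center
    v = np.asarray(nb2, float) - center
    w = np.asarray(target, float) - center
    return 1.0 if np.dot(np.cross(u, v), w) >= 0 else -1.0


@lru_cache(maxsize=None)
def _d_branch_signs() -> dict[str, float]:
    """Branch orientations for the exocyclic substituents of a D-ribose,
    measured once on the CCD adenosine reference."""
    from biotite.structure.info import residue as ccd_residue

    ccd = ccd_residue("A")
    pos = {n: np.asarray(ccd.coord[ccd.atom_name == n][0], float)
           for n in ("C1'", "C2'", "C3'", "C4'", "O4'", "O2'", "O3'", "C5'", "N9")}
    return {
        "N": _branch_sign(pos["C1'"], pos["O4'"], pos["C2'"], pos["N9"]),
        "O2'": _branch_sign(pos["C2'"], pos["C1'"], pos["C3'"], pos["O2'"]),
        "O3'": _branch_sign(pos["C3'"], pos["C4'"], pos["C2'"], pos["O3'"]),
        "C5'": _branch_sign(pos["C4'"], pos["C3'"], pos["O4'"], pos["C5'"]),
    }


def build_sugar(P: float = 18.0, vmax: float = DEFAULT_VMAX, gamma: float = 54.0,
                beta: float = 180.0, alpha: float = -68.0,
                with_phosphate: bool = True) -> dict[str, np.ndarray]:
    """Sugar-phosphate moiety plus the glycosidic nitrogen position (key "N")
    in a local frame.  The base itself is attached separately."""
    atoms = dict(build_ring(P, vmax))
    signs = _d_branch_signs()
    atoms["N"] = place_by_two_angles(atoms["C1'"], atoms["O4'"], atoms["C2'"],
                                     GLYCO_BOND, *GLYCO_ANGLES, branch=signs["N"])
    atoms["O2'"] = place_by_two_angles(atoms["C2'"], atoms["C1'"], atoms["C3'"],
                                       O2P_BOND, *O2P_ANGLES, branch=signs["O2'"])
    atoms["O3'"] = place_by_two_angles(atoms["C3'"], atoms["C4'"], atoms["C2'"],
                                       O3P_BOND, *O3P_ANGLES, branch=signs["O3'"])
    atoms["C5'"] = place_by_two_angles(atoms["C4'"], atoms["C3'"], atoms["O4'"],
                                       C5P_BOND, *C5P_ANGLES, branch=signs["C5'"])
    atoms["O5'"] = place_by_zmatrix(atoms["C3'"], atoms["C4'"], atoms["C5'"],
                                    O5P_BOND, O5P_ANGLE, gamma)
    if with_phosphate:
        atoms["P"] = place_by_zmatrix(atoms["C4'"], atoms["C5'"], atoms["O5'"],
                                      P_BOND, P_ANGLE, beta)
        # free 5'-phosphate: orient the OP oxygens from the alpha-like torsion
        virtual_o3 = place_by_zmatrix(atoms["C5'"], atoms["O5'"], atoms["P"],
                                      O3_P_BOND, O3_P_O5_ANGLE, alpha)
        place_op_oxygens(atoms, virtual_o3)
    return atoms


def place_op_oxygens(atoms: dict[str, np.ndarray], o3_prev: np.ndarray) -> None:
    """Set OP1/OP2 tetrahedrally on P given the two ester oxygens."""
    atoms["OP1"] = place_by_two_angles(atoms["P"], atoms["O5'"], o3_prev,
                                       OP_BOND, OP_ANGLE_O5, OP_ANGLE_O3, branch=1.0)
    atoms["OP2"] = place_by_two_angles(atoms["P"], atoms["O5'"], o3_prev,
                                       OP_BOND, OP_ANGLE_O5, OP_ANGLE_O3, branch=-1.0)


def attach_base(atoms: dict[str, np.ndarray], code: str, chi: float) -> dict[str, np.ndarray]:
    """Rigidly place the (flattened CCD) base of `code` on a sugar built by
    :func:`build_sugar`, at glycosidic torsion `chi`.

    Returns the complete heavy-atom dictionary (the helper key "N" is renamed
    to the proper N9/N1).
    """
    base = base_geometry(code)
    nname = GLYCOSIDIC_N[code]
    internal = _ccd_n_internal(code)
    ang = _base_attachment_angles(code)
    n = atoms["N"]
    cchi = place_by_zmatrix(atoms["O4'"], atoms["C1'"], n,
                            internal["bond_chi"], ang["angle_chi"], chi)
    cother = place_by_zmatrix(atoms["O4'"], atoms["C1'"], n,
                              internal["bond_other"], ang["angle_other"],
                              chi + ang["delta_other"])
    src = np.array([base[nname], base[CHI_BASE_ATOM[code]], base[OTHER_N_NEIGHBOUR[code]]])
    dst = np.array([n, cchi, cother])
    R, t = _rigid_fit_3pt(src, dst)
    out = {k: v for k, v in atoms.items() if k != "N"}
    for name in BASE_ATOMS[code]:
        out[name] = base[name] @ R.T + t
    return out


def _rigid_fit_3pt(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rigid transform taking the 3-point set src onto dst (Kabsch)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, cd - R @ cs


def build_nucleotide(code: str, *, P: float = 18.0, vmax: float = DEFAULT_VMAX,
                     chi: float = -160.0, gamma: float = 54.0, beta: float = 180.0,
                     alpha: float = -68.0,
                     five_prime_phosphate: bool = True) -> dict[str, np.ndarray]:
    """A complete ideal ribonucleotide (heavy atoms, local frame)."""
    sugar = build_sugar(P=P, vmax=vmax, gamma=gamma, beta=beta, alpha=alpha,
                        with_phosphate=five_prime_phosphate)
    atoms = attach_base(sugar, code, chi)
    order = heavy_atom_names(code, five_prime_phosphate)
    return {name: atoms[name] for name in order}


# ---------------------------------------------------------------------------
# Ideal Watson-Crick pair frame
# ---------------------------------------------------------------------------
#
# Pair frame: base planes at z=0; C1' anchors at (-+ C1C1/2, 0, 0); both
# glycosidic bonds make the lambda angle with the C1'-C1' axis, pointing to
# +y; the pair pseudo-dyad is the y axis (180 deg rotation about y swaps the
# two strands).  All four pair types share identical anchor geometry, which
# makes every pair isosteric and lets one sugar placement serve any sequence.

PAIR_DYAD = np.diag([-1.0, 1.0, -1.0])  # 180 deg about the pair-frame y axis


@dataclass(frozen=True)
class PairFrame:
    code1: str
    code2: str
    c1p: tuple[np.ndarray, np.ndarray]      # C1' anchors, strand 1 / strand 2
    n: tuple[np.ndarray, np.ndarray]        # glycosidic nitrogens
    base1: dict[str, np.ndarray]
    base2: dict[str, np.ndarray]
    hbond_names: tuple[tuple[str, str], ...]

    def hbond_distances(self) -> tuple[float, ...]:
        return tuple(float(np.linalg.norm(self.base1[a] - self.base2[b]))
                     for a, b in self.hbond_names)


def _anchor_points() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    half = C1C1_DISTANCE / 2.0
    lam = np.radians(LAMBDA_DEG)
    c1p_1 = np.array([-half, 0.0, 0.0])
    c1p_2 = np.array([half, 0.0, 0.0])
    n1 = c1p_1 + GLYCO_BOND * np.array([np.cos(lam), np.sin(lam), 0.0])
    n2 = c1p_2 + GLYCO_BOND * np.array([-np.cos(lam), np.sin(lam), 0.0])
    return c1p_1, c1p_2, n1, n2


def _place_base_in_plane(code: str, n_target: np.ndarray, theta: float,
                         flip: bool) -> dict[str, np.ndarray]:
    """Put the flattened base into the z=0 plane with its glycosidic N at
    `n_target`, rotated in-plane by theta.  `flip` mirrors the base through
    the plane (the two strands of an antiparallel pair face opposite ways)."""
    base = base_geometry(code)
    names = BASE_ATOMS[code]
    pts = np.array([base[nm] for nm in names])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    # local in-plane axes; for planar input the third axis is the normal
    ex, ey = vt[0], vt[1]
    local = np.stack([(pts - centroid) @ ex, (pts - centroid) @ ey], axis=1)
    if flip:
        local[:, 1] *= -1.0
    c, s = np.cos(np.radians(theta)), np.sin(np.radians(theta))
    rot = local @ np.array([[c, s], [-s, c]])
    n_idx = names.index(GLYCOSIDIC_N[code])
    rot -= rot[n_idx]
    coords = np.zeros((len(names), 3))
    coords[:, 0] = rot[:, 0] + n_target[0]
    coords[:, 1] = rot[:, 1] + n_target[1]
    return {nm: coords[i] for i, nm in enumerate(names)}


@lru_cache(maxsize=None)
def pair_frame(code1: str) -> PairFrame:
    """Ideal WC pair with strand-1 base `code1` (partner is its complement).

    The two in-plane base rotations are solved so every donor-acceptor
    contact sits as close to 2.9 angstrom as the rigid bases allow; the
    C1'/N anchor scaffold itself is fixed, which keeps all pair types exactly
    isosteric.  Non-canonical strand-1 codes (C, U) are derived from the
    canonical (G, A) pair by the pair dyad, so that the two orientations of
    one pair are exact images of each other.
    """
    code2 = WC_COMPLEMENT[code1]
    if code1 in ("C", "U"):
        swapped = pair_frame(code2)
        return PairFrame(
            code1=code1, code2=code2,
            c1p=(PAIR_DYAD @ swapped.c1p[1], PAIR_DYAD @ swapped.c1p[0]),
            n=(PAIR_DYAD @ swapped.n[1], PAIR_DYAD @ swapped.n[0]),
            base1={k: PAIR_DYAD @ v for k, v in swapped.base2.items()},
            base2={k: PAIR_DYAD @ v for k, v in swapped.base1.items()},
            hbond_names=WC_HBONDS[(code1, code2)],
        )

    c1p_1, c1p_2, n1, n2 = _anchor_points()
    hbonds = WC_HBONDS[(code1, code2)]

    # canonical glycosidic-bond orientation of each base, from the CCD itself
    def ccd_glyco_angle(code: str) -> float:
        from biotite.structure.info import residue as ccd_residue
        ccd = ccd_residue(code)
        pos = {n: np.asarray(ccd.coord[ccd.atom_name == n][0], float)
               for n in ("C1'", GLYCOSIDIC_N[code], CHI_BASE_ATOM[code])}
        return angle_deg(pos["C1'"], pos[GLYCOSIDIC_N[code]], pos[CHI_BASE_ATOM[code]])

    target_ang = (ccd_glyco_angle(code1), ccd_glyco_angle(code2))

    def solve(flip1: bool, flip2: bool):
        def build(thetas):
            b1 = _place_base_in_plane(code1, n1, thetas[0], flip=flip1)
            b2 = _place_base_in_plane(code2, n2, thetas[1], flip=flip2)
            return b1, b2

        def residuals(thetas):
            b1, b2 = build(thetas)
            res = [5.0 * (np.linalg.norm(b1[a] - b2[b]) - HBOND_TARGET)
                   for a, b in hbonds]
            res.append(2.0 * np.radians(
                angle_deg(c1p_1, n1, b1[CHI_BASE_ATOM[code1]]) - target_ang[0]))
            res.append(2.0 * np.radians(
                angle_deg(c1p_2, n2, b2[CHI_BASE_ATOM[code2]]) - target_ang[1]))
            return res

        # seed the in-plane rotations from a coarse deterministic scan
        grid = np.arange(0.0, 360.0, 15.0)
        best, best_val = (0.0, 0.0), np.inf
        for t1 in grid:
            for t2 in grid:
                v = float(np.sum(np.square(residuals((t1, t2)))))
                if v < best_val:
                    best_val, best = v, (t1, t2)
        sol = least_squares(residuals, np.array(best),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        b1, b2 = build(sol.x)
        return b1, b2, float(np.sum(np.square(residuals(sol.x))))

    def parity(base: dict[str, np.ndarray], code: str) -> float:
        n = base[GLYCOSIDIC_N[code]]
        v1 = base[CHI_BASE_ATOM[code]] - n
        v2 = base[OTHER_N_NEIGHBOUR[code]] - n
        return float(np.sign(np.cross(v1, v2)[2]))

    # Two flip combinations can satisfy the H-bond distances (a pair and its
    # in-plane mirror); the base-normal parity convention (+1 for strand 1,
    # -1 for strand 2) picks one deterministically so that every pair type
    # stacks consistently in a helix.
    chosen = None
    for f1 in (False, True):
        for f2 in (False, True):
            b1, b2, cost = solve(f1, f2)
            if cost < 2.0 and parity(b1, code1) > 0 and parity(b2, code2) < 0:
                if chosen is None or cost < chosen[2]:
                    chosen = (b1, b2, cost)
    if chosen is None:
        raise RuntimeError(f"no consistent WC pair geometry for {code1}-{code2}")
    b1, b2, _ = chosen
    return PairFrame(code1=code1, code2=code2, c1p=(c1p_1, c1p_2), n=(n1, n2),
                     base1=b1, base2=b2, hbond_names=hbonds)


@lru_cache(maxsize=None)
def _base_attachment_angles(code: str) -> dict[str, float]:
    """Angles tying the rigid base to the sugar, measured on the ideal pair
    frame so helix-built and template-built residues agree exactly."""
    pf = pair_frame(code)
    c1p, n = pf.c1p[0], pf.n[0]
    cchi = pf.base1[CHI_BASE_ATOM[code]]
    cother = pf.base1[OTHER_N_NEIGHBOUR[code]]
    # in the planar pair frame both torsions about C1'-N are well defined
    delta = wrap180(
        dihedral_deg(c1p + np.array([0, 0, 1.0]), c1p, n, cother)
        - dihedral_deg(c1p + np.array([0, 0, 1.0]), c1p, n, cchi)
    )
    return {
        "angle_chi": angle_deg(c1p, n, cchi),
        "angle_other": angle_deg(c1p, n, cother),
        "delta_other": float(delta),
    }


# ---------------------------------------------------------------------------
# Residue templates
# ---------------------------------------------------------------------------

#: chiral centres of the D-ribose: centre -> three ranked substituents.
#: ("N" stands for the glycosidic nitrogen of the residue.)
CHIRAL_CENTERS: tuple[tuple[str, tuple[str, str, str]], ...] = (
    ("C1'", ("O4'", "N", "C2'")),
    ("C2'", ("O2'", "C1'", "C3'")),
    ("C3'", ("O3'", "C2'", "C4'")),
    ("C4'", ("O4'", "C3'", "C5'")),
)


@dataclass(frozen=True)
class ResidueTemplate:
    """Ideal heavy-atom template of one ribonucleotide."""

    code: str
    coords: dict[str, np.ndarray] = field(repr=False)
    five_prime_phosphate: bool = True

    @property
    def heavy_atoms(self) -> tuple[str, ...]:
        return tuple(self.coords)

    @property
    def base_atoms(self) -> tuple[str, ...]:
        return BASE_ATOMS[self.code]

    def chiral_reference_signs(self) -> dict[str, float]:
        """Sign of the substituent scalar triple product at each sugar
        stereocentre for the D configuration."""
        out = {}
        nname = GLYCOSIDIC_N[self.code]
        for center, subs in CHIRAL_CENTERS:
            names = [nname if s == "N" else s for s in subs]
            c = self.coords[center]
            v = [self.coords[s] - c for s in names]
            out[center] = float(np.sign(np.dot(v[0], np.cross(v[1], v[2]))))
        return out


@lru_cache(maxsize=None)
def get_template(code: str, five_prime_phosphate: bool = True) -> ResidueTemplate:
    """The canonical (C3'-endo, anti) template used for ideal-geometry
    restraints, heavy-atom accounting and chirality references."""
    coords = build_nucleotide(code, five_prime_phosphate=five_prime_phosphate)
    return ResidueTemplate(code=code, coords=coords,
                           five_prime_phosphate=five_prime_phosphate)


@lru_cache(maxsize=None)
def d_reference_signs(code: str) -> dict[str, float]:
    """Computed once from the pinned template (not hard-coded)."""
    return get_template(code).chiral_reference_signs()
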