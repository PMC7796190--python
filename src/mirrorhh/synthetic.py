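"""Synthetic structure generation: ideal A/B-form duplexes, a hammerhead
two-strand analysis scaffold, coordinate perturbation, and seeded ensembles
with prescribed per-residue pseudorotation/chi distributions.

These generators stand in for externally modelled coordinates: they provide
topologically valid, Watson-Crick-detectable, all-D structures on which the
chirality and conformational analyses operate.  The hammerhead scaffold in
particular is an analysis test scaffold, NOT a physical fold prediction:
its helices are ideal A-form segments and the unpaired core is laid out on
smooth connecting arcs.

Helix construction works by exact helical symmetry.  One nucleotide template
per strand is solved (by least squares over its free internal/placement
parameters) such that applying the helical operator closes the backbone,
and the ideal Watson-Crick pair frame plus the pair dyad generate the
antiparallel partner strand.  The generator is deterministic: identical
inputs and seeds give identical structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from . import templates
from ._geom import dihedral_deg, normalize, rotation_about_axis, wrap360
from .structure_io import (
    ModelEnsemble,
    NucleotideResidue,
    RNAChain,
    StructureComplex,
)
from .templates import (
    DEFAULT_VMAX,
    GLYCOSIDIC_N,
    CHI_BASE_ATOM,
    PAIR_DYAD,
    WC_COMPLEMENT,
    build_ring,
    build_sugar,
    build_nucleotide,
    pair_frame,
    place_op_oxygens,
)

__all__ = [
    "HelixForm",
    "A_FORM",
    "B_FORM",
    "EnsembleSpec",
    "GenerationError",
    "build_duplex",
    "build_hammerhead_scaffold",
    "perturb",
    "generate_ensemble",
    "reverse_complement",
]


class GenerationError(RuntimeError):
    """Synthetic-structure generation failed (e.g. infeasible ring closure)."""


@dataclass(frozen=True)
class HelixForm:
    """Fibre-style helical parameters of an ideal duplex.

    A-form RNA uses C3'-endo sugars, B-form C2'-endo; the pinned twist/rise
    values are fibre-diffraction standards, and `pp_distance` is the adjacent
    intra-strand P-P distance the geometry is calibrated to reproduce.
    """

    name: str
    twist: float            # deg / step
    rise: float             # angstrom / step
    target_pucker: str      # "C3'-endo" or "C2'-endo"
    pucker_P: float         # pseudorotation phase realising the pucker
    pp_distance: float      # target adjacent P-P distance, angstrom
    chi0: float             # soft target for the glycosidic torsion
    gamma0: float           # soft target for gamma
    beta0: float            # soft target for beta

    def __post_init__(self):
        expected = "C3'-endo" if abs(self.pucker_P - 18.0) < 45 else "C2'-endo"
        if self.target_pucker != expected:
            raise ValueError("pucker class inconsistent with pseudorotation phase")


A_FORM = HelixForm(name="A", twist=32.7, rise=2.81, target_pucker="C3'-endo",
                   pucker_P=18.0, pp_distance=5.9, chi0=-160.0, gamma0=54.0,
                   beta0=180.0)
B_FORM = HelixForm(name="B", twist=36.0, rise=3.38, target_pucker="C2'-endo",
                   pucker_P=162.0, pp_distance=7.0, chi0=-120.0, gamma0=36.0,
                   beta0=160.0)


def reverse_complement(seq: str) -> str:
    return "".join(WC_COMPLEMENT[c] for c in reversed(seq))


def _check_sequence(seq: str) -> None:
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"sequence contains non-ACGU letters: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Helical template
# ---------------------------------------------------------------------------

def _pair_to_helix(dx: float, psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Rigid map (R, t) from pair-frame to helix-frame coordinates.

    The pair dyad (its y axis) is first aligned with the helix x axis, then
    slid outward by dx along it and rolled about it by psi (inclination).
    Keeping the dyad axis perpendicular to and intersecting the helix axis
    preserves the exact two-fold symmetry of the duplex.
    """
    Rz = rotation_about_axis([0, 0, 1.0], -90.0)
    Rx = rotation_about_axis([1.0, 0, 0], psi)
    R = Rx @ Rz
    t = Rx @ np.array([dx, 0.0, 0.0])
    return R, t


def _helical_op(form: HelixForm) -> tuple[np.ndarray, np.ndarray]:
    S = rotation_about_axis([0, 0, 1.0], form.twist)
    return S, np.array([0.0, 0.0, form.rise])


def _place_sugar(sugar: dict[str, np.ndarray], c1p_t: np.ndarray, n_t: np.ndarray,
                 up_hint: np.ndarray, tau: float) -> dict[str, np.ndarray]:
    """Rigidly place a local-frame sugar so C1' and the glycosidic nitrogen
    land on their targets; `tau` rolls the sugar about the glycosidic axis
    (measured from the `up_hint` direction)."""
    e1 = normalize(sugar["N"] - sugar["C1'"])
    ref = sugar["O4'"] - sugar["C1'"]
    e2 = normalize(ref - np.dot(ref, e1) * e1)
    e3 = np.cross(e1, e2)
    B_loc = np.stack([e1, e2, e3])

    f1 = normalize(n_t - c1p_t)
    up = up_hint - np.dot(up_hint, f1) * f1
    f2 = rotation_about_axis(f1, tau) @ normalize(up)
    f3 = np.cross(f1, f2)
    B_tgt = np.stack([f1, f2, f3])

    R = B_tgt.T @ B_loc
    return {k: R @ (v - sugar["C1'"]) + c1p_t for k, v in sugar.items()}


@lru_cache(maxsize=None)
def _helix_template(form_name: str) -> dict:
    """Solve the strand-1 nucleotide placement for a helix form.

    Free parameters: sugar roll about the glycosidic bond (tau), gamma, beta,
    the dyad-axis displacement dx and the inclination psi.  Hard residuals:
    backbone closure under the helical operator (O3'-P bond and its flanking
    angles) and the target adjacent P-P distance.  Soft residuals keep chi,
    gamma, beta near canonical values to select the physically sensible
    branch.  Returns pair-frame sugar coordinates plus solved parameters.
    """
    form = {f.name: f for f in (A_FORM, B_FORM)}[form_name]
    S, s_t = _helical_op(form)
    pf = pair_frame("G")  # anchors are identical for all pair types
    c1p_pf, n_pf = pf.c1p[0], pf.n[0]
    cchi_pf = pf.base1[CHI_BASE_ATOM["G"]]

    from ._geom import angle_deg

    def build(params):
        tau, gamma, beta, dx, psi = params
        sugar = build_sugar(P=form.pucker_P, vmax=DEFAULT_VMAX, gamma=gamma,
                            beta=beta, with_phosphate=True)
        R, t = _pair_to_helix(dx, psi)
        c1p_t = R @ c1p_pf + t
        n_t = R @ n_pf + t
        up = R @ np.array([0.0, 0.0, 1.0])
        placed = _place_sugar(sugar, c1p_t, n_t, up, tau)
        placed["_cchi"] = R @ cchi_pf + t
        return placed

    def residuals(params):
        a = build(params)
        p_next = S @ a["P"] + s_t
        o5_next = S @ a["O5'"] + s_t
        res = [
            50.0 * (np.linalg.norm(p_next - a["O3'"]) - templates.O3_P_BOND),
            50.0 * np.radians(angle_deg(a["C3'"], a["O3'"], p_next)
                              - templates.C3_O3_P_ANGLE),
            50.0 * np.radians(angle_deg(a["O3'"], p_next, o5_next)
                              - templates.O3_P_O5_ANGLE),
            50.0 * (np.linalg.norm((S @ a["P"] + s_t) - a["P"]) - form.pp_distance),
        ]
        chi = dihedral_deg(a["O4'"], a["C1'"], a["N"], a["_cchi"])
        res.append(0.05 * np.radians(chi - form.chi0))
        res.append(0.05 * np.radians(params[1] - form.gamma0))
        res.append(0.05 * np.radians(params[2] - form.beta0))
        return res

    best = None
    for tau0 in (0.0, 90.0, 180.0, 270.0):
        for dx0, psi0 in ((-4.0, 15.0), (-4.0, -15.0), (0.0, 0.0), (-2.0, 0.0)):
            x0 = np.array([tau0, form.gamma0, form.beta0, dx0, psi0])
            sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
    hard = residuals(best.x)[:4]
    if max(abs(r) for r in hard) > 0.5:
        raise GenerationError(
            f"helix template for form {form_name} failed to close: {hard}")

    placed = build(best.x)
    cchi = placed.pop("_cchi")
    chi = dihedral_deg(placed["O4'"], placed["C1'"], placed["N"], cchi)
    # phosphate oxygens from the previous residue's O3' (helical image)
    Sinv = S.T
    o3_prev = Sinv @ (placed["O3'"] - s_t)
    place_op_oxygens(placed, o3_prev)
    # store in pair-frame coordinates
    tau, gamma, beta, dx, psi = best.x
    R, t = _pair_to_helix(dx, psi)
    sugar_pf = {k: R.T @ (v - t) for k, v in placed.items()}
    return {
        "form": form, "sugar_pf": sugar_pf, "dx": float(dx), "psi": float(psi),
        "tau": float(tau), "gamma": float(gamma), "beta": float(beta),
        "chi": float(chi),
    }


def _pair_atoms(code: str) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Base heavy atoms of the two strands of an ideal pair, pair frame."""
    pf = pair_frame(code)
    return dict(pf.base1), dict(pf.base2)


def _strand_residue_atoms(code: str, tpl: dict, mate: bool) -> dict[str, np.ndarray]:
    """Pair-frame heavy atoms of one residue: universal sugar + its base.

    `mate=True` gives the dyad image (the antiparallel partner strand built
    on the complementary base)."""
    sugar = tpl["sugar_pf"]
    base1, _ = _pair_atoms(code)
    atoms = {k: v.copy() for k, v in sugar.items() if k != "N"}
    atoms.update(base1)
    if mate:
        atoms = {k: templates.PAIR_DYAD @ v for k, v in atoms.items()}
    return atoms


def _transform(atoms: dict[str, np.ndarray], R: np.ndarray,
               t: np.ndarray) -> dict[str, np.ndarray]:
    return {k: R @ v + t for k, v in atoms.items()}


def _order_atoms(code: str, atoms: dict[str, np.ndarray],
                 five_prime_phosphate: bool) -> dict[str, np.ndarray]:
    names = templates.heavy_atom_names(code, five_prime_phosphate)
    return {n: atoms[n] for n in names}


def build_duplex(seq: str, form: HelixForm = A_FORM,
                 chain_ids: tuple[str, str] = ("A", "B")) -> StructureComplex:
    """An ideal antiparallel duplex; strand 2 is the reverse complement.

    Every Watson-Crick pair satisfies the detection cutoffs, all sugars sit
    in the form's target pucker, and all residues are D.
    """
    seq = seq.upper()
    _check_sequence(seq)
    if len(seq) < 2:
        raise ValueError("duplex needs at least 2 base pairs")
    tpl = _helix_template(form.name)
    S, s_t = _helical_op(form)
    R_ph, t_ph = _pair_to_helix(tpl["dx"], tpl["psi"])

    n = len(seq)
    res1, res2 = [], []
    for i, code in enumerate(seq):
        Ri = np.linalg.matrix_power(S, i)
        ti = np.array([0.0, 0.0, form.rise * i])
        # strand 1 residue i+1
        a1 = _transform(_strand_residue_atoms(code, tpl, mate=False), R_ph, t_ph)
        a1 = _transform(a1, Ri, ti)
        res1.append((i + 1, code, a1))
        # strand 2 partner (5'->3' index n-i)
        code2 = WC_COMPLEMENT[code]
        a2 = _transform(_strand_residue_atoms(code2, tpl, mate=True), R_ph, t_ph)
        a2 = _transform(a2, Ri, ti)
        res2.append((n - i, code2, a2))

    res2.sort(key=lambda r: r[0])
    chains = []
    for cid, items in ((chain_ids[0], res1), (chain_ids[1], res2)):
        residues = []
        for k, (idx, code, atoms) in enumerate(items):
            atoms = _order_atoms(code, atoms, five_prime_phosphate=(k > 0))
            residues.append(NucleotideResidue.from_coords(idx, code, atoms))
        chains.append(RNAChain(chain_id=cid, residues=residues))
    out = StructureComplex(chains=chains)
    _label_chirality(out)
    return out


def _label_chirality(complex_: StructureComplex) -> None:
    from .chirality import classify_residue_chirality
    for res in complex_.residues():
        try:
            res.chirality = classify_residue_chirality(res)
        except ValueError:
            res.chirality = "unknown"


# ---------------------------------------------------------------------------
# Hammerhead scaffold
# ---------------------------------------------------------------------------

#: junction layout: helices 1 and 3 are laid out quasi-coaxially (the
#: substrate strand runs through both, as in the coaxial stem stacking of
#: real hammerheads) with helix 2 branching off; each arm's first pair sits
#: `offset` angstroms from the junction centre along its direction
_ARM_DIRECTIONS = {"H1": 0.0, "H2": 80.0, "H3": 180.0}
_ARM_OFFSETS = {"H1": 5.0, "H2": 18.0, "H3": 5.0}
_CLASH_FLOOR = 2.5


def _arm_transform(helix: str, roll_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Map helix-local coordinates (axis z) to a radial arm in the xy plane."""
    R = (rotation_about_axis([0, 0, 1.0], _ARM_DIRECTIONS[helix])
         @ rotation_about_axis([0, 1.0, 0], 90.0)
         @ rotation_about_axis([0, 0, 1.0], roll_deg))
    t = R @ np.array([0.0, 0.0, _ARM_OFFSETS[helix]])
    return R, t


def _solve_arm_rolls(tpl: dict, form: HelixForm) -> dict[str, float]:
    """Deterministic grid search for the roll of each arm about its own axis,
    keeping the junction-facing strand ends of neighbouring arms at arc-able
    distances (substrate continuity across the cleavage site, ribozyme core
    runs of 7 and 3 residues)."""
    S, s_t = _helical_op(form)
    R_ph, t_ph = _pair_to_helix(tpl["dx"], tpl["psi"])
    c1_s1 = R_ph @ tpl["sugar_pf"]["C1'"] + t_ph
    c1_s2 = R_ph @ (PAIR_DYAD @ tpl["sugar_pf"]["C1'"]) + t_ph

    def c1(helix, roll, mate, step):
        R_arm, t_arm = _arm_transform(helix, roll)
        base = c1_s2 if mate else c1_s1
        p = np.linalg.matrix_power(S, step) @ base + np.array([0, 0, form.rise * step])
        return R_arm @ p + t_arm

    grid = np.arange(0.0, 360.0, 15.0)
    best, best_J = None, np.inf
    for r1 in grid:
        p_sub10 = c1("H1", r1, mate=False, step=0)
        p_rz5 = c1("H1", r1, mate=True, step=0)
        for r3 in grid:
            p_sub8 = c1("H3", r3, mate=True, step=0)
            p_rz28 = c1("H3", r3, mate=False, step=0)
            j13 = (np.linalg.norm(p_sub8 - p_sub10) - 12.0) ** 2
            for r2 in grid:
                p_rz13 = c1("H2", r2, mate=False, step=0)
                p_rz24 = c1("H2", r2, mate=True, step=0)
                J = (j13
                     + 0.3 * (np.linalg.norm(p_rz5 - p_rz13) - 25.0) ** 2
                     + 0.3 * (np.linalg.norm(p_rz24 - p_rz28) - 18.0) ** 2)
                if J < best_J:
                    best_J, best = J, {"H1": float(r1), "H2": float(r2),
                                       "H3": float(r3)}
    return best


def _arc_points(p0: np.ndarray, p1: np.ndarray, n: int, bulge: float,
                bow: np.ndarray) -> list[np.ndarray]:
    """n interior points, evenly spaced in arc length, on a quadratic arc
    from p0 to p1 bowed by `bulge` angstroms along the unit vector `bow`."""
    ctrl = 0.5 * (p0 + p1) + bulge * bow
    s = np.linspace(0.0, 1.0, 257)[:, None]
    dense = (1 - s) ** 2 * p0 + 2 * s * (1 - s) * ctrl + s ** 2 * p1
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n + 2)[1:-1]
    idx = np.searchsorted(cum, targets)
    return [dense[min(i, len(dense) - 1)] for i in idx]


def _place_free_nucleotide(code: str, position: np.ndarray, tangent: np.ndarray,
                           outward: np.ndarray | None = None,
                           five_prime_phosphate: bool = True) -> dict[str, np.ndarray]:
    """A template nucleotide rigidly set down at `position` with its backbone
    roughly along `tangent`; the base is rolled toward `outward` to keep the
    crowded junction interior clear (used for unpaired core/loop residues)."""
    nt = build_nucleotide(code, five_prime_phosphate=five_prime_phosphate)
    o5 = nt["O5'"] if "O5'" in nt else nt["C5'"]
    d_loc = normalize(nt["O3'"] - o5)
    t_hat = normalize(tangent)
    v = np.cross(d_loc, t_hat)
    s = np.linalg.norm(v)
    c = float(np.dot(d_loc, t_hat))
    if s < 1e-9:
        R = np.eye(3) if c > 0 else rotation_about_axis([1.0, 0, 0], 180.0)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    if outward is not None and np.linalg.norm(outward) > 1e-6:
        nname = GLYCOSIDIC_N[code]
        glyco = R @ (nt[nname] - nt["C1'"])
        # roll about the tangent so the glycosidic bond points outward
        out_p = normalize(outward - np.dot(outward, t_hat) * t_hat) \
            if np.linalg.norm(outward - np.dot(outward, t_hat) * t_hat) > 1e-6 else None
        gl_p = glyco - np.dot(glyco, t_hat) * t_hat
        if out_p is not None and np.linalg.norm(gl_p) > 1e-6:
            gl_p = normalize(gl_p)
            ang = np.degrees(np.arctan2(float(np.dot(np.cross(gl_p, out_p), t_hat)),
                                        float(np.dot(gl_p, out_p))))
            R = rotation_about_axis(t_hat, ang) @ R
    c1 = nt["C1'"]
    return {k: R @ (p - c1) + position for k, p in nt.items()}


def build_hammerhead_scaffold(ribozyme_seq: str, substrate_seq: str,
                              pairing) -> StructureComplex:
    """All-D two-chain hammerhead scaffold with ideal A-form helices 1-3 and
    unpaired core residues on smooth connecting arcs.

    Chain "R" is the ribozyme, chain "S" the substrate; both 5' termini are
    free 5'-OH.  The contract is topological validity and Watson-Crick
    detectability of every mapped pair -- not physical realism of the core.
    """
    ribozyme_seq = ribozyme_seq.upper()
    substrate_seq = substrate_seq.upper()
    _check_sequence(ribozyme_seq)
    _check_sequence(substrate_seq)

    helices = {h: pairing.helix_pairs(h) for h in ("H1", "H2", "H3")}
    for h, pairs in helices.items():
        if not pairs:
            raise ValueError(f"pairing map lacks helix {h}")
        for pair in pairs:
            for cid, idx in (pair.res_a, pair.res_b):
                seq = ribozyme_seq if cid == "R" else substrate_seq
                if not (1 <= idx <= len(seq)):
                    raise IndexError(f"pair references residue {cid}/{idx} "
                                     f"outside the sequences")

    coords: dict[tuple[str, int], tuple[str, dict[str, np.ndarray]]] = {}
    tpl = _helix_template("A")
    form = A_FORM
    S, s_t = _helical_op(form)
    R_ph, t_ph = _pair_to_helix(tpl["dx"], tpl["psi"])

    # Strand-1 of each arm runs 5'->3' away from the junction core:
    # H1 -- the substrate 3' flank; H2 -- the stem 5' side; H3 -- the
    # ribozyme 3' arm.  The core-proximal pair sits nearest the centre so
    # the connecting arcs stay short.
    strand1_chain = {"H1": "S", "H2": "R", "H3": "R"}
    rolls = _solve_arm_rolls(tpl, form)
    for h, pairs in helices.items():
        R_arm, t_arm = _arm_transform(h, rolls[h])
        s1 = strand1_chain[h]

        def s1_ref(pair):
            return pair.res_a if pair.res_a[0] == s1 else pair.res_b

        pairs_sorted = sorted(pairs, key=lambda p: s1_ref(p)[1])
        for i, pair in enumerate(pairs_sorted):
            Ri = np.linalg.matrix_power(S, i)
            ti = np.array([0.0, 0.0, form.rise * i])
            ref1 = s1_ref(pair)
            ref2 = pair.res_b if ref1 == pair.res_a else pair.res_a
            (cid_a, idx_a), (cid_b, idx_b) = ref1, ref2
            code_a = (ribozyme_seq if cid_a == "R" else substrate_seq)[idx_a - 1]
            code_b = (ribozyme_seq if cid_b == "R" else substrate_seq)[idx_b - 1]
            if WC_COMPLEMENT[code_a] != code_b:
                raise ValueError(f"non-complementary pair {cid_a}{idx_a}-{cid_b}{idx_b}")
            a1 = _transform(_strand_residue_atoms(code_a, tpl, mate=False), R_ph, t_ph)
            a2 = _transform(_strand_residue_atoms(code_b, tpl, mate=True), R_ph, t_ph)
            for (cid, idx, atoms) in ((cid_a, idx_a, a1), (cid_b, idx_b, a2)):
                atoms = _transform(atoms, Ri, ti)
                atoms = _transform(atoms, R_arm, t_arm)
                coords[(cid, idx)] = (
                    (ribozyme_seq if cid == "R" else substrate_seq)[idx - 1], atoms)

    # unpaired residues on connecting arcs between their flanking anchors
    free_keys: set[tuple[str, int]] = set()

    def anchor(cid: str, idx: int) -> np.ndarray | None:
        entry = coords.get((cid, idx))
        return entry[1]["C1'"].copy() if entry else None

    for cid, seq in (("R", ribozyme_seq), ("S", substrate_seq)):
        free_runs: list[list[int]] = []
        run: list[int] = []
        for idx in range(1, len(seq) + 1):
            if (cid, idx) not in coords:
                run.append(idx)
            elif run:
                free_runs.append(run)
                run = []
        if run:
            free_runs.append(run)
        for run in free_runs:
            p0 = anchor(cid, run[0] - 1)
            p1 = anchor(cid, run[-1] + 1)
            if p0 is None and p1 is None:
                raise GenerationError(f"chain {cid}: no anchors for free run {run}")
            bow = None
            if p0 is None:  # dangling 5' end: extend outward from the anchor
                radial = p1.copy(); radial[2] = 0.0
                bow = normalize(radial if np.linalg.norm(radial) > 1e-6
                                else np.array([1.0, 0, 0]))
                pts = [p1 + 6.0 * bow * (len(run) - k) for k in range(len(run))]
            elif p1 is None:  # dangling 3' end
                radial = p0.copy(); radial[2] = 0.0
                bow = normalize(radial if np.linalg.norm(radial) > 1e-6
                                else np.array([1.0, 0, 0]))
                pts = [p0 + 6.0 * bow * (k + 1) for k in range(len(run))]
            else:
                gap = float(np.linalg.norm(p1 - p0))
                arclen = 7.0 * (len(run) + 1)
                bulge = 0.5 * np.sqrt(max(arclen ** 2 - gap ** 2, 25.0))
                # candidate bow directions; greedily keep the one whose arc
                # stays farthest from everything placed so far
                mid = 0.5 * (p0 + p1)
                radial = mid.copy(); radial[2] = 0.0
                cands = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])]
                if np.linalg.norm(radial) > 1e-6:
                    cands.append(normalize(radial))
                placed = np.array([p for (_c, at) in coords.values()
                                   for p in at.values()])
                from scipy.spatial import cKDTree
                tree = cKDTree(placed)
                best_pts, best_score, best_bow = None, -np.inf, None
                for cand in cands:
                    pts_c = _arc_points(p0, p1, len(run), bulge, cand)
                    score = float(np.min(tree.query(np.array(pts_c))[0]))
                    if score > best_score:
                        best_score, best_pts, best_bow = score, pts_c, cand
                pts, bow = best_pts, best_bow
            for idx, pt, nxt in zip(run, pts, pts[1:] + [p1 if p1 is not None else None]):
                tangent = (nxt - pt) if nxt is not None else (pt - pts[0] if len(pts) > 1
                                                              else np.array([1.0, 0, 0]))
                if np.linalg.norm(tangent) < 1e-6:
                    tangent = np.array([1.0, 0.0, 0.0])
                atoms = _place_free_nucleotide(seq[idx - 1], pt, tangent, outward=bow)
                coords[(cid, idx)] = (seq[idx - 1], atoms)
                free_keys.add((cid, idx))

    _relax_free_clashes(coords, free_keys)

    chains = []
    for cid, seq in (("R", ribozyme_seq), ("S", substrate_seq)):
        residues = []
        for idx in range(1, len(seq) + 1):
            code, atoms = coords[(cid, idx)]
            atoms = _order_atoms(code, atoms, five_prime_phosphate=(idx > 1))
            residues.append(NucleotideResidue.from_coords(idx, code, atoms))
        chains.append(RNAChain(chain_id=cid, residues=residues))
    out = StructureComplex(chains=chains)
    _label_chirality(out)
    _check_clashes(out)
    return out


def _relax_free_clashes(coords: dict, free_keys: set,
                        floor: float = _CLASH_FLOOR + 0.15,
                        max_iter: int = 80) -> None:
    """Rigid-body repulsion of arc-placed residues until no non-bonded
    contact sits under the clash floor (deterministic, helices untouched)."""
    from scipy.spatial import cKDTree

    for _ in range(max_iter):
        atom_list = [(k, p) for k, (_c, atoms) in coords.items()
                     for p in atoms.values()]
        xyz = np.array([p for _, p in atom_list])
        keys = [k for k, _ in atom_list]
        tree = cKDTree(xyz)
        shift = {k: np.zeros(3) for k in free_keys}
        nbad = 0
        for i, j in tree.query_pairs(r=floor):
            ki, kj = keys[i], keys[j]
            if ki == kj:
                continue
            if ki[0] == kj[0] and abs(ki[1] - kj[1]) == 1:
                continue
            if ki not in shift and kj not in shift:
                continue
            d = xyz[i] - xyz[j]
            dist = float(np.linalg.norm(d))
            direction = d / dist if dist > 1e-9 else np.array([1.0, 0.0, 0.0])
            push = 0.6 * (floor - dist) * direction
            nbad += 1
            if ki in shift:
                shift[ki] += push
            if kj in shift:
                shift[kj] -= push
        if nbad == 0:
            return
        for k, v in shift.items():
            if np.linalg.norm(v) > 1e-9:
                code, atoms = coords[k]
                coords[k] = (code, {n: p + v for n, p in atoms.items()})


def _check_clashes(complex_: StructureComplex, floor: float = _CLASH_FLOOR) -> None:
    """Warn (via exception-free report) if non-bonded atoms sit closer than
    the clash floor; helix interiors are exempt (their contacts are bonded or
    paired)."""
    recs = list(complex_.atom_records())
    xyz = np.array([a.position for _, _, a in recs])
    keys = [(c.chain_id, r.index) for c, r, _ in recs]
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    close = tree.query_pairs(r=floor)
    bad = 0
    for i, j in close:
        ci, cj = keys[i], keys[j]
        if ci == cj:
            continue  # intra-residue contacts are covalent
        if ci[0] == cj[0] and abs(ci[1] - cj[1]) == 1:
            continue  # bonded neighbours
        bad += 1
    if bad:
        import warnings
        warnings.warn(f"scaffold has {bad} non-bonded contacts under "
                      f"{floor} angstrom", stacklevel=2)


# ---------------------------------------------------------------------------
# Perturbation and ensembles
# ---------------------------------------------------------------------------

def perturb(complex_: StructureComplex, sigma: float, seed: int) -> StructureComplex:
    """I.i.d. Gaussian displacement of every coordinate (sd = sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = complex_.copy()
    if sigma == 0.0:
        return out
    rng = np.random.default_rng(seed)
    coords = out.coords()
    out.set_all_coords(coords + rng.normal(0.0, sigma, size=coords.shape))
    return out


@dataclass
class EnsembleSpec:
    """Prescription for a seeded conformational ensemble.

    P/chi means and standard deviations may be scalars (applied to every
    residue) or sequences with one entry per residue (complex order).
    Identical seeds give identical ensembles.
    """

    n_models: int
    p_mean: float | list[float] = 18.0
    p_sd: float | list[float] = 0.0
    chi_mean: float | list[float] = -160.0
    chi_sd: float | list[float] = 0.0
    noise_sd: float = 0.0
    vmax: float = DEFAULT_VMAX
    seed: int = 0

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        for v in (self.p_sd, self.chi_sd, self.noise_sd):
            arr = np.atleast_1d(np.asarray(v, dtype=float))
            if np.any(arr < 0):
                raise ValueError("standard deviations must be >= 0")

    @classmethod
    def from_dict(cls, payload: dict) -> "EnsembleSpec":
        return cls(**payload)

    @classmethod
    def from_json(cls, text: str) -> "EnsembleSpec":
        return cls.from_dict(json.loads(text))

    def _per_residue(self, value, n: int) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(n, float(arr))
        if arr.shape != (n,):
            raise ValueError(f"per-residue parameter needs length {n}, got {arr.shape}")
        return arr


def _resample_residue(res: NucleotideResidue, P: float, chi: float,
                      vmax: float) -> None:
    """Rebuild the sugar ring at pseudorotation P and rotate the base to chi,
    keeping the residue anchored at its current ring position."""
    from .compare_analyze import kabsch_superpose  # local import avoids cycle

    try:
        # quantize to a 0.25-degree grid so repeated draws share cached ring
        # solutions (negligible next to the prescribed spread of P)
        new_ring = build_ring(round(P * 4.0) / 4.0, vmax)
    except Exception as exc:  # infeasible closure
        raise GenerationError(
            f"residue {res.code}{res.index}: ring closure failed at "
            f"P={P:.1f}, vmax={vmax:.1f}: {exc}") from exc
    old = res.coords(templates.RING_ORDER)
    new = np.array([new_ring[n] for n in templates.RING_ORDER])
    fit = kabsch_superpose(new, old, allow_reflection=False)
    placed = new @ fit.rotation.T + fit.translation
    ring_coords = {n: placed[i] for i, n in enumerate(templates.RING_ORDER)}

    # remember current exocyclic torsions before touching anything
    gamma = dihedral_deg(res["O5'"], res["C5'"], res["C4'"], res["C3'"]) \
        if "O5'" in res else 54.0
    beta = dihedral_deg(res["P"], res["O5'"], res["C5'"], res["C4'"]) \
        if "P" in res and "O5'" in res else 180.0

    res.set_coords(ring_coords)
    signs = templates._d_branch_signs()
    from ._geom import place_by_two_angles, place_by_zmatrix
    r = {n: res[n] for n in templates.RING_ORDER}
    res.set_coords({
        "O2'": place_by_two_angles(r["C2'"], r["C1'"], r["C3'"],
                                   templates.O2P_BOND, *templates.O2P_ANGLES,
                                   branch=signs["O2'"]),
        "O3'": place_by_two_angles(r["C3'"], r["C4'"], r["C2'"],
                                   templates.O3P_BOND, *templates.O3P_ANGLES,
                                   branch=signs["O3'"]),
        "C5'": place_by_two_angles(r["C4'"], r["C3'"], r["O4'"],
                                   templates.C5P_BOND, *templates.C5P_ANGLES,
                                   branch=signs["C5'"]),
    })
    if "O5'" in res:
        res.set_coords({"O5'": place_by_zmatrix(res["C3'"], res["C4'"], res["C5'"],
                                                templates.O5P_BOND,
                                                templates.O5P_ANGLE, gamma)})
    if "P" in res:
        res.set_coords({"P": place_by_zmatrix(res["C4'"], res["C5'"], res["O5'"],
                                              templates.P_BOND, templates.P_ANGLE,
                                              beta)})

    # re-anchor the base: translate so N keeps its ideal position on the new
    # C1', then roll about the glycosidic bond to the requested chi
    nname = GLYCOSIDIC_N[res.code]
    n_new = place_by_two_angles(r["C1'"], r["O4'"], r["C2'"], templates.GLYCO_BOND,
                                *templates.GLYCO_ANGLES, branch=signs["N"])
    shift = n_new - res[nname]
    base_names = res.base_atom_names()
    res.set_coords({b: res[b] + shift for b in base_names})
    chi_now = dihedral_deg(res["O4'"], res["C1'"], res[nname],
                           res[CHI_BASE_ATOM[res.code]])
    axis = res[nname] - res["C1'"]
    R = rotation_about_axis(axis, chi - chi_now)
    pivot = res[nname]
    res.set_coords({b: R @ (res[b] - pivot) + pivot for b in base_names})


def generate_ensemble(complex_: StructureComplex, spec: EnsembleSpec) -> ModelEnsemble:
    """Seeded multi-model ensemble with per-residue P and chi drawn from
    wrapped normal distributions and optional Cartesian noise."""
    residues = list(complex_.residues())
    n_res = len(residues)
    p_mean = spec._per_residue(spec.p_mean, n_res)
    p_sd = spec._per_residue(spec.p_sd, n_res)
    chi_mean = spec._per_residue(spec.chi_mean, n_res)
    chi_sd = spec._per_residue(spec.chi_sd, n_res)
    rng = np.random.default_rng(spec.seed)

    members = []
    for _ in range(spec.n_models):
        frame = complex_.copy()
        frame_res = list(frame.residues())
        ps = wrap360(rng.normal(p_mean, p_sd))
        chis = rng.normal(chi_mean, chi_sd)
        for res, P, chi in zip(frame_res, ps, chis):
            _resample_residue(res, float(P), float(chi), spec.vmax)
        if spec.noise_sd > 0.0:
            coords = frame.coords()
            frame.set_all_coords(coords + rng.normal(0.0, spec.noise_sd,
                                                     size=coords.shape))
        members.append(frame)
    return ModelEnsemble(members=members)
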