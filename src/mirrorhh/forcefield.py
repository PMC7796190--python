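"""Torsion/improper force-field parameter tables and their
enantiomerization.

L-nucleotide parameters differ from the D ones only in the terms that are
sensitive to handedness: every chirality-enforcing improper force constant
changes sign, and every torsion phase offset is negated (delta in {0, 180}
being the achiral fixed points).  Bond, angle and non-bonded terms are
achiral and shared.  The torsion-energy evaluator exists to make the claim
checkable: the total torsion+improper energy is invariant under
simultaneously mirroring a structure and enantiomerizing the parameters.

Parameter files use a small frcmod-like text dialect (DIHE / IMPROPER
section headers, whitespace-separated records); unknown sections are
preserved verbatim for round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._geom import dihedral_deg, wrap360
from .structure_io import StructureComplex

__all__ = [
    "TorsionTerm",
    "ImproperTerm",
    "ParameterSet",
    "ParameterParseError",
    "parse_parameters",
    "write_parameters",
    "enantiomerize",
    "torsion_energy",
]


class ParameterParseError(ValueError):
    pass


@dataclass(frozen=True)
class TorsionTerm:
    """Proper torsion: E = k * (1 + cos(n*phi - delta))."""

    atom_types: tuple[str, str, str, str]
    k: float            # kcal/mol
    periodicity: int    # n in 1..6
    phase: float        # delta, degrees

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("torsion barrier k must be >= 0")
        if not (1 <= int(self.periodicity) <= 6):
            raise ValueError("periodicity must be in 1..6")


@dataclass(frozen=True)
class ImproperTerm:
    """Improper torsion (centre atom third by convention).

    Periodic form: E = k * (1 + cos(n*xi - delta)) with signed k.
    Harmonic form (periodicity 0): E = k * (xi - xi0)^2, with xi0 = phase.
    """

    atom_types: tuple[str, str, str, str]
    k: float            # signed
    periodicity: int    # 0 marks the harmonic form
    phase: float        # delta (periodic) or xi0 (harmonic), degrees

    @property
    def harmonic(self) -> bool:
        return self.periodicity == 0


@dataclass
class ParameterSet:
    torsions: list[TorsionTerm] = field(default_factory=list)
    impropers: list[ImproperTerm] = field(default_factory=list)
    provenance: str = "D"   # {D, L}
    extra_sections: dict[str, list[str]] = field(default_factory=dict)
    title: str = ""


def _neg_phase(delta: float) -> float:
    # rounded so that double negation is exactly the identity
    return round(float(wrap360(-delta)), 9)


def enantiomerize(params: ParameterSet) -> ParameterSet:
    """Derive the mirror-image parameter set.

    Improper force constants change sign (periodic form) or their reference
    angle is negated (harmonic form); torsion phases are negated modulo 360
    (0 and 180 are fixed points); barrier heights and periodicities are
    untouched.  The operation is an involution.
    """
    torsions = [replace(t, phase=_neg_phase(t.phase)) for t in params.torsions]
    impropers = []
    for im in params.impropers:
        if im.harmonic:
            impropers.append(replace(im, phase=_neg_phase(im.phase)))
        else:
            impropers.append(replace(im, k=-im.k, phase=_neg_phase(im.phase)))
    return ParameterSet(
        torsions=torsions, impropers=impropers,
        provenance="L" if params.provenance == "D" else "D",
        extra_sections={k: list(v) for k, v in params.extra_sections.items()},
        title=params.title)


# ---------------------------------------------------------------------------
# frcmod-like dialect
# ---------------------------------------------------------------------------

_SECTION_NAMES = ("MASS", "BOND", "ANGLE", "DIHE", "IMPROPER", "NONBON")


def _parse_types(tok: str) -> tuple[str, str, str, str]:
    parts = [p.strip() for p in tok.split("-")]
    if len(parts) != 4 or not all(parts):
        raise ValueError(f"bad atom-type quadruple {tok!r}")
    return tuple(parts)  # type: ignore[return-value]


def parse_parameters(path) -> ParameterSet:
    """Parse a frcmod-like file into a typed ParameterSet.

    DIHE records: ``T1-T2-T3-T4  divider  k  phase  periodicity`` (the
    AMBER idivf divider column is accepted and folded into k) or the
    4-column variant without the divider.  IMPROPER records:
    ``T1-T2-T3-T4  k  phase  periodicity`` with periodicity 0 for the
    harmonic form.  Unknown sections are kept verbatim.
    """
    text = open(path).read() if not hasattr(path, "read") else path.read()
    lines = text.splitlines()
    if not lines:
        raise ParameterParseError("empty parameter file")
    pset = ParameterSet(title=lines[0].strip()
                        if lines and not lines[0].strip().upper().startswith(_SECTION_NAMES)
                        else "")
    section = None
    seen_section = False
    start = 1 if pset.title else 0
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        line = raw.rstrip()
        stripped = line.strip()
        if not stripped:
            continue
        upper = stripped.upper()
        if upper.startswith(_SECTION_NAMES):
            section = next(s for s in _SECTION_NAMES if upper.startswith(s))
            seen_section = True
            continue
        if section is None:
            raise ParameterParseError(
                f"line {lineno}: record before any section header: {stripped!r}")
        try:
            if section == "DIHE":
                toks = stripped.split()
                types = _parse_types(toks[0])
                nums = [float(t) for t in toks[1:5]]
                if len(nums) == 4:
                    divider, k, phase, per = nums
                    k = k / divider if divider else k
                else:
                    k, phase, per = nums[:3]
                pset.torsions.append(TorsionTerm(types, k, abs(int(round(per))), phase))
            elif section == "IMPROPER":
                toks = stripped.split()
                types = _parse_types(toks[0])
                k, phase, per = (float(t) for t in toks[1:4])
                pset.impropers.append(ImproperTerm(types, k, abs(int(round(per))), phase))
            else:
                pset.extra_sections.setdefault(section, []).append(line)
        except (ValueError, IndexError) as exc:
            raise ParameterParseError(f"line {lineno}: {exc}") from exc
    if not seen_section:
        raise ParameterParseError("no section headers (DIHE/IMPROPER/...) found")
    return pset


def write_parameters(params: ParameterSet, path) -> None:
    lines = [params.title or f"{params.provenance}-RNA torsion/improper parameters"]
    for name, body in params.extra_sections.items():
        lines.append(name)
        lines.extend(body)
        lines.append("")
    lines.append("DIHE")
    for t in params.torsions:
        lines.append(f"{'-'.join(t.atom_types):<16} 1 {t.k:10.5f} {t.phase:10.3f} "
                     f"{t.periodicity:4d}")
    lines.append("")
    lines.append("IMPROPER")
    for im in params.impropers:
        lines.append(f"{'-'.join(im.atom_types):<16} {im.k:12.5f} {im.phase:10.3f} "
                     f"{im.periodicity:4d}")
    lines.append("")
    out = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(out)
    else:
        with open(path, "w") as fh:
            fh.write(out)


# ---------------------------------------------------------------------------
# Torsion-energy evaluator
# ---------------------------------------------------------------------------

def torsion_energy(complex_: StructureComplex, params: ParameterSet,
                   torsion_assignment: dict) -> float:
    """Sum of proper and improper torsion energies (kcal/mol).

    `torsion_assignment` maps atom quadruples -- tuples of
    (chain_id, residue_index, atom_name) -- to a TorsionTerm/ImproperTerm or
    a list of them.  Each assigned term is resolved against `params` by its
    atom types and periodicity, so one assignment serves both a parameter
    set and its enantiomerized counterpart; unresolvable terms raise.
    """
    lookup: dict[tuple, object] = {}
    for t in params.torsions:
        lookup[(t.atom_types, t.periodicity, "torsion")] = t
    for t in params.impropers:
        lookup[(t.atom_types, t.periodicity, "improper")] = t

    def atom_pos(key):
        cid, ridx, aname = key
        res = complex_.chain(cid).residue(ridx)
        if aname not in res:
            raise KeyError(f"assignment error: missing atom {key}")
        return res[aname]

    total = 0.0
    for quad, terms in torsion_assignment.items():
        if terms is None:
            raise ValueError(f"assignment error: quadruple {quad} has no term")
        terms_iter = terms if isinstance(terms, (list, tuple)) else [terms]
        pts = [atom_pos(k) for k in quad]
        phi = dihedral_deg(*pts)
        for assigned in terms_iter:
            kind = "improper" if isinstance(assigned, ImproperTerm) else "torsion"
            term = lookup.get((assigned.atom_types, assigned.periodicity, kind))
            if term is None:
                raise ValueError(
                    f"assignment error: no {kind} term for types "
                    f"{assigned.atom_types} (n={assigned.periodicity}) in set")
            if isinstance(term, ImproperTerm) and term.harmonic:
                from ._geom import wrap180
                dev = np.radians(wrap180(phi - term.phase))
                total += term.k * float(dev) ** 2
            else:
                total += term.k * (1.0 + np.cos(np.radians(
                    term.periodicity * phi - term.phase)))
    return float(total)
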