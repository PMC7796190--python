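"""RNA 3D structure data model and (multi-model) PDB reading/writing.

Heavy atoms only: hydrogens are never stored.  Residues are renumbered
1..n per chain, 5'->3'.  Atom names follow PDB v3 with ``'`` as the prime
character; ``*`` and the typographic prime are accepted on input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import templates

__all__ = [
    "Atom3D",
    "NucleotideResidue",
    "RNAChain",
    "StructureComplex",
    "ModelEnsemble",
    "PDBFormatError",
    "EnsembleError",
    "read_pdb",
    "write_pdb",
    "sequence_of",
    "load_sequence",
]


class PDBFormatError(ValueError):
    """Unparsable or unsupported PDB content."""


class EnsembleError(ValueError):
    """MODEL blocks with inconsistent topology."""


#: residue-name dialects accepted on input
_RESNAME_ALIASES = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U",
    "RA": "A", "RC": "C", "RG": "G", "RU": "U",
    "RA3": "A", "RC3": "C", "RG3": "G", "RU3": "U",
    "RA5": "A", "RC5": "C", "RG5": "G", "RU5": "U",
}

_LEGACY_ATOM_NAMES = {"O1P": "OP1", "O2P": "OP2"}


def normalize_atom_name(name: str) -> str:
    name = name.strip().replace("*", "'").replace("′", "'")
    return _LEGACY_ATOM_NAMES.get(name, name)


def element_of(atom_name: str) -> str:
    """Element symbol implied by a PDB v3 nucleic-acid atom name."""
    stripped = atom_name.strip("0123456789'")
    return stripped[0] if stripped else atom_name[0]


@dataclass
class Atom3D:
    """A named heavy atom with a position in angstroms."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class NucleotideResidue:
    """One ribonucleotide: 1-based index (5'->3'), code, heavy atoms."""

    index: int
    code: str
    atoms: dict[str, Atom3D] = field(default_factory=dict)
    chirality: str = "unknown"  # {D, L, invalid, unknown}

    @classmethod
    def from_coords(cls, index: int, code: str,
                    coords: dict[str, np.ndarray]) -> "NucleotideResidue":
        atoms = {n: Atom3D(n, element_of(n), p) for n, p in coords.items()}
        return cls(index=index, code=code, atoms=atoms)

    def __getitem__(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name].position

    def __contains__(self, atom_name: str) -> bool:
        return atom_name in self.atoms

    @property
    def five_prime_phosphate(self) -> bool:
        return "P" in self.atoms

    def atom_names(self) -> tuple[str, ...]:
        return tuple(self.atoms)

    def coords(self, names=None) -> np.ndarray:
        names = names if names is not None else self.atoms
        return np.array([self.atoms[n].position for n in names])

    def set_coords(self, coords: dict[str, np.ndarray]) -> None:
        for n, p in coords.items():
            self.atoms[n].position = np.asarray(p, dtype=float)

    def base_atom_names(self) -> tuple[str, ...]:
        return templates.BASE_ATOMS[self.code]

    def validate_against_template(self) -> None:
        allowed = set(templates.heavy_atom_names(self.code, True))
        extra = set(self.atoms) - allowed
        if extra:
            raise ValueError(
                f"residue {self.code}{self.index} has non-template atoms: {sorted(extra)}")

    def copy(self) -> "NucleotideResidue":
        return NucleotideResidue(
            index=self.index, code=self.code,
            atoms={n: Atom3D(a.name, a.element, a.position.copy())
                   for n, a in self.atoms.items()},
            chirality=self.chirality)


@dataclass
class RNAChain:
    chain_id: str
    residues: list[NucleotideResidue] = field(default_factory=list)

    @property
    def five_prime_phosphate(self) -> bool:
        return bool(self.residues) and self.residues[0].five_prime_phosphate

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def residue(self, index: int) -> NucleotideResidue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"chain {self.chain_id}: no residue {index}")

    def copy(self) -> "RNAChain":
        return RNAChain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class StructureComplex:
    """An RNA complex: one or more chains of nucleotide residues."""

    chains: list[RNAChain] = field(default_factory=list)

    def __iter__(self):
        return iter(self.chains)

    def chain(self, chain_id: str) -> RNAChain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def residues(self):
        for c in self.chains:
            yield from c.residues

    def atom_records(self):
        """Yield (chain, residue, atom) over all heavy atoms, in order."""
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms.values():
                    yield c, r, a

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords(self) -> np.ndarray:
        return np.array([a.position for _, _, a in self.atom_records()])

    def set_all_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.atom_count(), 3):
            raise ValueError("coordinate array shape mismatch")
        for (_, _, a), row in zip(self.atom_records(), coords):
            a.position = row.copy()

    def topology_key(self):
        return tuple(
            (c.chain_id, tuple((r.index, r.code, tuple(sorted(r.atoms))) for r in c))
            for c in self.chains)

    def copy(self) -> "StructureComplex":
        return StructureComplex([c.copy() for c in self.chains])


@dataclass
class ModelEnsemble:
    """Ordered, topology-identical structures (frames/models)."""

    members: list[StructureComplex] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i) -> StructureComplex:
        return self.members[i]

    def validate(self) -> None:
        if not self.members:
            return
        ref = self.members[0].topology_key()
        for i, m in enumerate(self.members[1:], start=2):
            key = m.topology_key()
            if key != ref:
                detail = _topology_diff(ref, key)
                raise EnsembleError(f"MODEL {i} topology differs from MODEL 1: {detail}")


def _topology_diff(ref, other) -> str:
    for (cid_a, res_a), (cid_b, res_b) in zip(ref, other):
        if cid_a != cid_b:
            return f"chain id {cid_b!r} vs {cid_a!r}"
        for ra, rb in zip(res_a, res_b):
            if ra != rb:
                return f"residue {rb[1]}{rb[0]} in chain {cid_a}"
        if len(res_a) != len(res_b):
            return f"residue count in chain {cid_a}"
    return "chain list"


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def read_pdb(path, model_policy: str = "all") -> ModelEnsemble:
    """Read a (multi-model) PDB file into a :class:`ModelEnsemble`.

    Hydrogens are discarded, atom names normalized (``*``/prime -> ``'``,
    O1P/O2P -> OP1/OP2), residues renumbered 1..n per chain.  Unknown
    residues are reported via a warning, never silently dropped.
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc

    members = []
    unknown: list[str] = []
    for model in st:
        chains = []
        for ch in model:
            residues = []
            for res in ch:
                code = _RESNAME_ALIASES.get(res.name.strip().upper())
                if code is None:
                    unknown.append(f"{ch.name}/{res.name}{res.seqid.num}")
                    continue
                atoms = {}
                for at in res:
                    if at.element.name in ("H", "D"):
                        continue
                    name = normalize_atom_name(at.name)
                    if not np.all(np.isfinite([at.pos.x, at.pos.y, at.pos.z])):
                        raise PDBFormatError(
                            f"non-finite coordinates for {ch.name}/{res.name}/{name}")
                    atoms[name] = Atom3D(name, at.element.name or element_of(name),
                                         np.array([at.pos.x, at.pos.y, at.pos.z]))
                if atoms:
                    residues.append(NucleotideResidue(index=len(residues) + 1,
                                                      code=code, atoms=atoms))
            if residues:
                chains.append(RNAChain(chain_id=ch.name[:1] or "A", residues=residues))
        members.append(StructureComplex(chains=chains))
        if model_policy == "first":
            break
    if unknown:
        warnings.warn(f"skipped non-RNA residues: {', '.join(unknown)}", stacklevel=2)
    if not members or not any(m.chains for m in members):
        raise PDBFormatError(f"{path}: no RNA residues found")
    return ModelEnsemble(members=members)


def write_pdb(ensemble: ModelEnsemble | StructureComplex, path) -> None:
    """Write an ensemble as PDB; MODEL/ENDMDL blocks only for >1 members."""
    if isinstance(ensemble, StructureComplex):
        ensemble = ModelEnsemble(members=[ensemble])
    ensemble.validate()
    n_atoms = ensemble.members[0].atom_count() if ensemble.members else 0
    if n_atoms > 99999:
        raise ValueError(f"unsupported size: {n_atoms} atoms exceeds PDB limit")

    st = gemmi.Structure()
    st.name = "mirrorhh"
    for i, member in enumerate(ensemble.members, start=1):
        model = gemmi.Model(i)
        for chain in member.chains:
            gchain = gemmi.Chain(chain.chain_id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = res.code
                gres.seqid = gemmi.SeqId(res.index, " ")
                for atom in res.atoms.values():
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.position)
                    ga.occ = 1.0
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            model.add_chain(gchain)
        st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


def sequence_of(chain: RNAChain) -> str:
    """The 5'->3' sequence read off the residues."""
    return "".join(r.code for r in chain.residues)


def load_sequence(source) -> str:
    """Read an RNA sequence from FASTA or plain text (file path or string)."""
    text = None
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    else:
        text = str(source)
    text = text.strip()
    if text.startswith(">"):
        lines = [ln.strip() for ln in text.splitlines()[1:] if not ln.startswith(">")]
        text = "".join(lines)
    seq = "".join(text.split()).upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"sequence contains non-RNA letters: {sorted(bad)}")
    return seq
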