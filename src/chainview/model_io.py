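"""Coordinate-file parsing into a typed chain/residue/atom hierarchy.

The reader wraps :mod:`gemmi` and flattens its structure into small
dataclasses that carry exactly what the validation metrics need: atom
names, elements (proton numbers), positions, B-factors and occupancies.
Alternate conformations are collapsed to a single conformer per atom name
(highest occupancy wins, ties broken by file order) so that every
per-residue metric is single-valued.  Only the first MODEL block of a
multi-model file is read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "StructureModel",
    "EmptyModelError",
    "ModelParseError",
    "STANDARD_AMINO_ACIDS",
    "read_model",
    "structure_to_model",
    "is_amino_acid",
]

#: The 20 canonical amino-acid three-letter codes.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_BACKBONE_REQUIRED = frozenset({"N", "CA", "C"})


class ModelParseError(RuntimeError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyModelError(ModelParseError):
    """Raised when a coordinate file contains no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom after altloc collapsing.

    position is in Å, b_factor in Å², proton_number is the element's Z.
    """

    name: str
    element: str
    proton_number: int
    position: np.ndarray
    b_factor: float
    occupancy: float
    altloc: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float)
        )
        if self.proton_number < 1:
            raise ValueError(f"proton_number must be >= 1, got {self.proton_number}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """One monomer: author numbering plus its (altloc-collapsed) atoms."""

    seq_num: int
    insertion_code: str
    name: str
    atoms: list[AtomRecord]
    het: bool = False

    @property
    def id(self) -> tuple[int, str]:
        return (self.seq_num, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def atom_names(self) -> frozenset[str]:
        return frozenset(a.name for a in self.atoms)

    @property
    def is_amino_acid(self) -> bool:
        return is_amino_acid(self)

    def label(self, chain_id: str = "") -> str:
        icode = self.insertion_code.strip()
        base = f"{self.seq_num}{icode}"
        return f"{chain_id}/{base}" if chain_id else base


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def amino_acids(self) -> list[Residue]:
        return [r for r in self.residues if r.is_amino_acid]


@dataclass
class StructureModel:
    """A parsed model: chains plus optional data resolution (Å)."""

    chains: list[Chain]
    resolution: float | None = None
    source_path: str = ""

    def __iter__(self):
        return iter(self.chains)

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


def is_amino_acid(
    residue: Residue, allow_het: frozenset[str] = frozenset()
) -> bool:
    """Decide whether a residue is analyzable as an amino acid.

    True iff the residue name is one of the 20 standard codes (or in the
    ``allow_het`` allow-list for non-standard types such as MSE) and the
    backbone atoms N, CA and C are all present.  HETATM residues are
    rejected unless allow-listed.
    """
    if residue.het and residue.name not in allow_het:
        return False
    if residue.name not in STANDARD_AMINO_ACIDS and residue.name not in allow_het:
        return False
    return _BACKBONE_REQUIRED <= residue.atom_names


def _collapse_altlocs(gemmi_residue: gemmi.Residue) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties → first."""
    best: dict[str, tuple[float, int, gemmi.Atom]] = {}
    order: list[str] = []
    for i, atom in enumerate(gemmi_residue):
        key = atom.name
        if key not in best:
            best[key] = (atom.occ, i, atom)
            order.append(key)
        elif atom.occ > best[key][0]:
            best[key] = (atom.occ, best[key][1], atom)
    records = []
    for key in order:
        _, _, atom = best[key]
        altloc = atom.altloc if atom.altloc not in ("\x00", " ") else ""
        records.append(
            AtomRecord(
                name=atom.name,
                element=atom.element.name,
                proton_number=max(1, atom.element.atomic_number),
                position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                b_factor=atom.b_iso,
                occupancy=atom.occ,
                altloc=altloc,
            )
        )
    return records


def read_model(path: str) -> StructureModel:
    """Parse a PDB (or mmCIF) file into a :class:`StructureModel`.

    Raises :class:`ModelParseError` on unreadable input and
    :class:`EmptyModelError` when the file contains no atoms.
    """
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ModelParseError(f"cannot parse coordinate file {path!r}: {exc}") from exc
    return structure_to_model(structure, source_path=str(path))


def structure_to_model(
    structure: gemmi.Structure, source_path: str = ""
) -> StructureModel:
    """Convert an in-memory gemmi Structure (first MODEL block only)."""
    path = source_path or structure.name
    if len(structure) == 0:
        raise EmptyModelError(f"no MODEL blocks in {path!r}")

    first = structure[0]  # only the first MODEL block
    chains: list[Chain] = []
    for gchain in first:
        residues = []
        for gres in gchain:
            atoms = _collapse_altlocs(gres)
            if not atoms:
                continue
            residues.append(
                Residue(
                    seq_num=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    name=gres.name,
                    atoms=atoms,
                    het=(gres.het_flag == "H"),
                )
            )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    model = StructureModel(
        chains=chains,
        resolution=structure.resolution if structure.resolution > 0 else None,
        source_path=path,
    )
    if model.n_atoms == 0:
        raise EmptyModelError(f"empty model: no atoms in {path!r}")
    return model
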