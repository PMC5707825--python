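"""Molecular structure data model and PDB-format I/O.

The reader applies the cleanup rules the clash test assumes: only the
first model of an ensemble is kept, hydrogens (and deuteriums) are
dropped, waters are removed, and one alternate-location conformer is
selected per atom (highest occupancy; ties prefer altloc "A", then the
lexicographically first).  Selenomethionine (MSE) is mapped to Met so it
stays part of the polymer; other nonstandard polymer residues are kept
as hetero atoms and remain clash partners.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.PDB import PDBParser as _BioPDBParser

from ._aa import AA3_TO_AA1, AA1_TO_AA3, WATER_NAMES, is_sidechain_atom
from .errors import (
    EmptyStructureError,
    IncompleteBackboneError,
    PDBParseError,
    PositionNotFoundError,
)

__all__ = [
    "AtomRecord",
    "ResidueSite",
    "Structure",
    "Variant",
    "load_radii_table",
    "parse_pdb",
    "read_pdb_file",
    "write_pdb",
    "get_site",
]


def load_radii_table() -> dict[str, float]:
    """Element -> van der Waals radius (A) from the packaged data file."""
    text = resources.files("clashscan.data").joinpath("vdw_radii.json").read_text()
    raw = json.loads(text)
    return {k: float(v) for k, v in raw.items() if not k.startswith("_")}


_RADII = load_radii_table()


def radius_for_element(element: str, table: dict[str, float] | None = None) -> float:
    table = _RADII if table is None else table
    return table.get(element.upper(), table.get("default", 1.80))


@dataclass(eq=False)
class AtomRecord:
    """One heavy atom with its residue context."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    vdw_radius: float = 0.0
    chain_id: str = ""
    res_name: str = ""
    res_seq: int = 0
    icode: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.element.upper() in ("H", "D"):
            raise ValueError("hydrogen atoms are not representable after cleanup")
        if self.vdw_radius == 0.0:
            self.vdw_radius = radius_for_element(self.element)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)


@dataclass(eq=False)
class ResidueSite:
    """A substitutable position: one polymer residue and its context.

    phi/psi are in degrees in (-180, 180] or None when undefined (chain
    termini, chain breaks).  sidechain_rel_acc is the side-chain SASA
    divided by the residue type's maximum; filled in by the predictor's
    preparation pass and None until then.
    """

    chain_id: str
    seq_number: int
    insertion_code: str
    res_type: str  # one-letter code
    atoms: list[AtomRecord] = field(default_factory=list)
    phi: float | None = None
    psi: float | None = None
    sidechain_rel_acc: float | None = None

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise IncompleteBackboneError(
                f"residue {self.chain_id}:{self.seq_number}{self.insertion_code} "
                f"lacks atom {name}"
            )
        return a.coords

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def sidechain_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if is_sidechain_atom(a.name)]


@dataclass(eq=False)
class Structure:
    """A cleaned structure: polymer residues plus retained hetero atoms."""

    residues: list[ResidueSite] = field(default_factory=list)
    hetero_atoms: list[AtomRecord] = field(default_factory=list)
    source_id: str = ""
    _prepared: bool = field(default=False, repr=False, compare=False)

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain_residues(self, chain_id: str) -> list[ResidueSite]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def all_atoms(self) -> list[AtomRecord]:
        out: list[AtomRecord] = []
        for r in self.residues:
            out.extend(r.atoms)
        out.extend(self.hetero_atoms)
        return out


@dataclass(frozen=True)
class Variant:
    """One requested substitution; to_aa None means 'all 19'."""

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    from_aa: str | None = None
    to_aa: str | None = None

    def __post_init__(self) -> None:
        if self.from_aa is not None and self.from_aa == self.to_aa:
            raise ValueError("substitution to the identical residue is not a variant")

    @property
    def is_position_only(self) -> bool:
        return self.to_aa is None


def _prevalidate(text: str) -> None:
    """Raise PDBParseError with a line number on malformed ATOM records."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM/HETATM record")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: bad coordinate field ({exc})") from exc


def _select_altloc(children: list) -> "object":
    """Highest occupancy; ties prefer altloc 'A', then lexicographic."""
    def sort_key(atom):
        occ = atom.get_occupancy() or 0.0
        alt = atom.get_altloc()
        return (-occ, 0 if alt == "A" else 1, alt)

    return sorted(children, key=sort_key)[0]


def parse_pdb(text: str, source_id: str = "") -> Structure:
    """Parse PDB-format text into a cleaned :class:`Structure`.

    Keeps model 1 only, drops hydrogens and waters, resolves alternate
    locations, maps MSE to Met, and routes nonstandard polymer residues
    and ligands into ``hetero_atoms``.
    """
    _prevalidate(text)
    parser = _BioPDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            bio = parser.get_structure(source_id or "input", io.StringIO(text))
        except Exception as exc:  # Biopython raises several types
            raise PDBParseError(f"unreadable PDB text: {exc}") from exc
    models = list(bio)
    if not models:
        raise EmptyStructureError("no model found in PDB text")
    model = models[0]

    structure = Structure(source_id=source_id)
    serial = 0
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.id
            resname = res.get_resname().strip()
            if resname in WATER_NAMES or hetflag == "W":
                continue
            is_mse = resname == "MSE"
            aa1 = AA3_TO_AA1.get("MET" if is_mse else resname)
            atoms: list[AtomRecord] = []
            for atom in res:
                if atom.is_disordered():
                    atom = _select_altloc(atom.disordered_get_list())
                element = (atom.element or atom.get_name()[0]).upper()
                if element in ("H", "D"):
                    continue
                name = atom.get_name()
                if is_mse and name == "SE":
                    name, element = "SD", "S"
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=element,
                        coords=np.array(atom.get_coord(), dtype=float),
                        occupancy=atom.get_occupancy() or 0.0,
                        altloc=atom.get_altloc().strip(),
                        is_hetero=(aa1 is None),
                        chain_id=chain.id.strip(),
                        res_name="MET" if is_mse else resname,
                        res_seq=resseq,
                        icode=icode.strip(),
                    )
                )
            if not atoms:
                continue
            if aa1 is None:
                structure.hetero_atoms.extend(atoms)
            else:
                structure.residues.append(
                    ResidueSite(
                        chain_id=chain.id.strip(),
                        seq_number=resseq,
                        insertion_code=icode.strip(),
                        res_type=aa1,
                        atoms=atoms,
                    )
                )
    if not structure.residues and not structure.hetero_atoms:
        raise EmptyStructureError("structure is empty after cleanup")
    return structure


def read_pdb_file(path) -> Structure:
    with open(path) as fh:
        text = fh.read()
    name = getattr(path, "stem", None) or str(path)
    return parse_pdb(text, source_id=name)


def _format_atom_name(name: str, element: str) -> str:
    # wwPDB v3.3: element right-justified in cols 13-14 for 1-char elements
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(record: str, a: AtomRecord, serial: int) -> str:
    x, y, z = a.coords
    return (
        f"{record:<6s}{serial:>5d} {_format_atom_name(a.name, a.element)}"
        f"{'':1s}{a.res_name:>3s} {a.chain_id or 'A':1s}{a.res_seq:>4d}"
        f"{a.icode or '':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}"
        f"{0.0:6.2f}          {a.element:>2s}  "
    )


def write_pdb(structure: Structure) -> str:
    """Serialize a structure back to PDB text (polymer ATOM, ligands HETATM)."""
    if not structure.residues and not structure.hetero_atoms:
        raise EmptyStructureError("cannot write an empty structure")
    lines: list[str] = []
    serial = 0
    for chain_id in structure.chains():
        last = None
        for res in structure.chain_residues(chain_id):
            for a in res.atoms:
                serial += 1
                lines.append(_atom_line("ATOM", a, serial))
            last = res
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {serial:>5d}      {last.atoms[0].res_name:>3s} "
                f"{chain_id or 'A':1s}{last.seq_number:>4d}{last.insertion_code or '':1s}"
            )
    for a in structure.hetero_atoms:
        serial += 1
        lines.append(_atom_line("HETATM", a, serial))
    lines.append("END")
    return "\n".join(lines) + "\n"


def get_site(structure: Structure, chain: str, seq_number: int, icode: str = "") -> ResidueSite:
    """Resolve a variant position to its residue.

    Raises PositionNotFoundError when no residue matches (typically a
    numbering mismatch between variant list and structure) and
    IncompleteBackboneError when the match lacks N, CA or C.
    """
    for res in structure.residues:
        if res.key == (chain, seq_number, icode):
            if not res.has_backbone:
                raise IncompleteBackboneError(
                    f"residue {chain}:{seq_number}{icode} lacks a complete "
                    "N/CA/C backbone"
                )
            return res
    raise PositionNotFoundError(
        f"no residue {chain}:{seq_number}{icode!r} in structure "
        f"{structure.source_id!r} (check chain and author numbering)"
    )
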