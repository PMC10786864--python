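"""Atomic data model and PDB-format I/O.

The pipeline operates on multi-chain macromolecular structures: polymer
chains (from ATOM records) plus bound small molecules (HETATM records,
waters excluded).  Author residue numbering, including insertion codes,
is preserved throughout because downstream mutation mapping and interface
reporting are expressed in author numbers.

Parsing is delegated to :mod:`gemmi`; a light pre-validation pass
enforces line-numbered errors for malformed coordinate fields, which the
underlying reader tolerates silently.  Only the first model of a
multi-model file is read, and for alternate locations the
highest-occupancy conformer is kept (ties broken toward altloc ``A``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "VdwTable",
    "StructureParseError",
    "EmptyStructureError",
    "parse_structure",
    "write_structure",
    "chain_sequence",
    "filter_short_chains",
]


class StructureParseError(ValueError):
    """Raised for malformed structure records; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyStructureError(ValueError):
    """Raised when a file yields no chains at all."""


# Standard 20 amino acids; everything else (MSE, ligand codes, ...) maps to X.
THREE_TO_ONE: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    """A single atom site with author metadata."""

    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    serial: int = 0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError("atom coordinate must be a finite 3-vector")
        if not self.element:
            raise ValueError("atom element must be non-empty")


@dataclass
class Residue:
    """A residue identified by its author number and insertion code."""

    name: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    is_polymer: bool = True

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def atoms(self) -> Iterable[Atom]:
        for r in self.residues:
            yield from r.atoms

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms()], dtype=float)


@dataclass
class StructureModel:
    entry_id: str
    chains: list[Chain] = field(default_factory=list)
    source: str = "experimental"  # or "predicted"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.entry_id}: duplicate chain ids")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"{self.entry_id}: no chain {chain_id!r}")

    def all_ligands(self) -> Iterable[tuple[str, Residue]]:
        for c in self.chains:
            for lig in c.ligands:
                yield c.id, lig


# Element radii follow a standard published set; unknown elements fall
# back to carbon-like 1.70 A.  Overridable via config key `vdw_table`.
_DEFAULT_VDW = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}


class VdwTable:
    """Van der Waals radii per element with a fallback default."""

    def __init__(self, radii: Mapping[str, float] | None = None,
                 default: float = 1.70):
        table = dict(_DEFAULT_VDW)
        if radii:
            table.update({k.upper(): float(v) for k, v in radii.items()})
        if default <= 0 or any(v <= 0 for v in table.values()):
            raise ValueError("van der Waals radii must be positive")
        self._radii = table
        self.default = float(default)

    def radius(self, element: str) -> float:
        return self._radii.get(element.upper(), self.default)

    @property
    def max_radius(self) -> float:
        return max(max(self._radii.values()), self.default)

    @classmethod
    def from_config(cls, config: Mapping) -> "VdwTable":
        """Build from a config mapping with optional ``vdw_table`` key."""
        sub = config.get("vdw_table", {}) if config else {}
        default = sub.pop("default", 1.70) if isinstance(sub, dict) else 1.70
        return cls(sub or None, default=default)


def _validate_coordinate_fields(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6] not in ("ATOM  ", "HETATM"):
            continue
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise StructureParseError(
                    f"malformed {what} coordinate field {fieldtxt!r}", lineno
                ) from None


def _select_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; tie prefers altloc 'A'/blank."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        cur = by_name.get(atom.name)
        if cur is None:
            by_name[atom.name] = atom
            continue
        alt = atom.altloc or "A"
        cur_alt = cur.altloc or "A"
        if (atom.occ, -ord(alt[0])) > (cur.occ, -ord(cur_alt[0])):
            by_name[atom.name] = atom
    return list(by_name.values())


def parse_structure(text: str, entry_id: str | None = None,
                    source: str = "experimental") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Polymer residues come from ATOM records, ligands from HETATM records;
    waters (HOH) are discarded.  Only the first model is read.

    Raises
    ------
    StructureParseError
        If a coordinate field cannot be parsed (names the line).
    EmptyStructureError
        If no chains result.
    """
    _validate_coordinate_fields(text)
    st = gemmi.read_pdb_string(text)
    if entry_id is None:
        entry_id = st.name.strip() or "XXXX"
    if len(st) == 0:
        raise EmptyStructureError(f"{entry_id}: no models in file")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            if gres.name == "HOH":
                continue
            atoms = []
            for gatom in _select_altloc(gres):
                pos = gatom.pos
                atoms.append(Atom(
                    name=gatom.name,
                    element=gatom.element.name or "C",
                    coord=np.array([pos.x, pos.y, pos.z]),
                    serial=gatom.serial,
                    occupancy=gatom.occ,
                ))
            if not atoms:
                continue
            is_polymer = gres.het_flag != "H"
            residue = Residue(
                name=gres.name,
                number=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                atoms=atoms,
                is_polymer=is_polymer,
            )
            (chain.residues if is_polymer else chain.ligands).append(residue)
        if chain.residues or chain.ligands:
            chains.append(chain)
    if not chains:
        raise EmptyStructureError(f"{entry_id}: structure contains no chains")
    return StructureModel(entry_id=entry_id, chains=chains, source=source)


def _format_record(kind: str, serial: int, atom: Atom, res: Residue,
                   chain_id: str) -> str:
    if not -999 <= res.number <= 9999:
        raise OverflowError(
            f"residue number {res.number} does not fit the 4-digit PDB field"
        )
    name = atom.name
    # one-letter elements start in column 14 by convention
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.coord
    return (
        f"{kind:<6s}{serial:5d} {name:<4s} {res.name:>3s} {chain_id:1s}"
        f"{res.number:4d}{res.icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_structure(model: StructureModel) -> str:
    """Serialize to fixed-width PDB ATOM/HETATM records (re-parsable)."""
    lines: list[str] = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_record("ATOM", serial, atom, res, chain.id))
        lines.append(f"TER   {serial + 1:5d}")
    for chain in model.chains:
        for res in chain.ligands:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_record("HETATM", serial, atom, res, chain.id))
    lines.append("END")
    return "\n".join(lines) + "\n"


def chain_sequence(chain: Chain) -> str:
    """One-letter sequence of the polymer residues in author-number order.

    Non-standard residues (including MSE) map to ``X``.
    """
    if not chain.residues:
        raise ValueError(f"chain {chain.id}: no polymer residues")
    ordered = sorted(chain.residues, key=lambda r: r.key)
    return "".join(THREE_TO_ONE.get(r.name, "X") for r in ordered)


def filter_short_chains(models: Sequence[StructureModel],
                        min_len: int = 30) -> list[StructureModel]:
    """Drop protein chains with fewer than ``min_len`` polymer residues.

    Ligand-only chains are not proteins and are exempt.  Structures left
    without chains are dropped entirely; removals are logged so the
    elimination step is auditable.
    """
    kept: list[StructureModel] = []
    for model in models:
        chains = []
        for chain in model.chains:
            if len(chain.residues) >= min_len or \
                    (not chain.residues and chain.ligands):
                chains.append(chain)
            else:
                logger.info(
                    "filter_short_chains: removed %s chain %s (%d residues < %d)",
                    model.entry_id, chain.id, len(chain.residues), min_len,
                )
        if chains:
            kept.append(StructureModel(model.entry_id, chains, model.source))
        else:
            logger.info("filter_short_chains: removed entire entry %s",
                        model.entry_id)
    return kept
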