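"""Atomic contact detection, interface extraction, ligand mapping.

Two atoms on different chains are in contact when their distance is
strictly less than the sum of their van der Waals radii plus a 0.5 A
tolerance.  A chain pair forms an interface when at least five residues
on *each* side participate in contacts.  A ligand is bound at an
interface when any of its atoms lies within 5 A of any interface-residue
atom.

Contact search is grid-accelerated with a KD-tree pruned at the largest
possible contact distance; the exact per-pair radius criterion is then
applied, so results are identical to the all-pairs computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import Chain, Residue, StructureModel, VdwTable

logger = logging.getLogger(__name__)

__all__ = [
    "ContactPair",
    "Interface",
    "LigandBinding",
    "atomic_contacts",
    "extract_interface",
    "enumerate_interfaces",
    "ligand_at_interface",
    "filter_fda_ligands",
    "write_interface_table",
    "write_binding_table",
]

EXCLUDED_CRYO_ADDITIVES = frozenset({"GOL", "IPA"})

ResidueKey = tuple[int, str]  # (author number, insertion code)


@dataclass(frozen=True)
class ContactPair:
    residue_a: ResidueKey
    residue_b: ResidueKey
    min_dist: float

    def __post_init__(self) -> None:
        if self.min_dist <= 0:
            raise ValueError("contact distance must be positive")


@dataclass
class Interface:
    id: str
    entry_id: str
    chain_a: str
    chain_b: str
    contacts: list[ContactPair]
    residues_a: frozenset[ResidueKey] = field(init=False)
    residues_b: frozenset[ResidueKey] = field(init=False)

    def __post_init__(self) -> None:
        self.residues_a = frozenset(c.residue_a for c in self.contacts)
        self.residues_b = frozenset(c.residue_b for c in self.contacts)

    def side_of(self, chain_id: str, key: ResidueKey) -> str | None:
        if chain_id == self.chain_a and key in self.residues_a:
            return "chain_a"
        if chain_id == self.chain_b and key in self.residues_b:
            return "chain_b"
        return None


@dataclass
class LigandBinding:
    ligand_code: str
    ligand_instance: tuple[str, int, str]  # (chain, number, icode)
    interface_id: str
    bound_side: str  # chain_a | chain_b | both
    contact_residues: frozenset[tuple[str, ResidueKey]]  # (side, key)

    def __post_init__(self) -> None:
        if not self.contact_residues:
            raise ValueError("ligand binding must have contact residues")
        sides = {side for side, _ in self.contact_residues}
        expected = "both" if len(sides) == 2 else next(iter(sides))
        if self.bound_side != expected:
            raise ValueError("bound_side inconsistent with contact residues")


def _chain_atom_arrays(chain: Chain, vdw: VdwTable):
    coords, radii, keys = [], [], []
    for res in chain.residues:
        for atom in res.atoms:
            coords.append(atom.coord)
            radii.append(vdw.radius(atom.element))
            keys.append(res.key)
    if not coords:
        raise ValueError(f"chain {chain.id} has no atoms")
    return np.asarray(coords), np.asarray(radii), keys


def atomic_contacts(chain_a: Chain, chain_b: Chain, vdw: VdwTable,
                    tol: float = 0.5) -> list[ContactPair]:
    """Residue-level contacts between two chains (strict vdW + tol rule)."""
    if chain_a.id == chain_b.id:
        raise ValueError("contacts require two distinct chains")
    coords_a, radii_a, keys_a = _chain_atom_arrays(chain_a, vdw)
    coords_b, radii_b, keys_b = _chain_atom_arrays(chain_b, vdw)
    max_cut = 2.0 * vdw.max_radius + tol
    tree_b = cKDTree(coords_b)
    neighbors = cKDTree(coords_a).query_ball_tree(tree_b, r=max_cut)
    best: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for ia, hits in enumerate(neighbors):
        if not hits:
            continue
        d = np.linalg.norm(coords_b[hits] - coords_a[ia], axis=1)
        cutoffs = radii_a[ia] + radii_b[hits] + tol
        for ib, dist, cut in zip(hits, d, cutoffs):
            if dist < cut:  # strict inequality per the contact rule
                pair = (keys_a[ia], keys_b[ib])
                if dist < best.get(pair, np.inf):
                    best[pair] = dist
    return [ContactPair(a, b, d) for (a, b), d in sorted(best.items())]


def extract_interface(model_entry: str, chain_a: Chain, chain_b: Chain,
                      vdw: VdwTable, tol: float = 0.5,
                      min_residues: int = 5) -> Interface | None:
    """Interface between two chains, or None if either side has fewer
    than ``min_residues`` contacting residues."""
    contacts = atomic_contacts(chain_a, chain_b, vdw, tol)
    n_a = len({c.residue_a for c in contacts})
    n_b = len({c.residue_b for c in contacts})
    if n_a < min_residues or n_b < min_residues:
        return None
    first, second = sorted([chain_a.id, chain_b.id])
    if first != chain_a.id:
        contacts = [ContactPair(c.residue_b, c.residue_a, c.min_dist)
                    for c in contacts]
    return Interface(
        id=f"{model_entry}_{first}_{second}",
        entry_id=model_entry,
        chain_a=first,
        chain_b=second,
        contacts=sorted(contacts, key=lambda c: (c.residue_a, c.residue_b)),
    )


def enumerate_interfaces(model: StructureModel, vdw: VdwTable,
                         tol: float = 0.5,
                         min_residues: int = 5) -> list[Interface]:
    """All pairwise interfaces of a structure, ids in lexicographic chain order."""
    interfaces = []
    chains = sorted(model.chains, key=lambda c: c.id)
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            if not chains[i].residues or not chains[j].residues:
                continue
            iface = extract_interface(model.entry_id, chains[i], chains[j],
                                      vdw, tol, min_residues)
            if iface is not None:
                interfaces.append(iface)
    return interfaces


def _interface_residue_atoms(model: StructureModel, interface: Interface):
    coords, labels = [], []
    for side, chain_id, keys in (
        ("chain_a", interface.chain_a, interface.residues_a),
        ("chain_b", interface.chain_b, interface.residues_b),
    ):
        chain = model.chain(chain_id)
        for res in chain.residues:
            if res.key in keys:
                for atom in res.atoms:
                    coords.append(atom.coord)
                    labels.append((side, res.key))
    return np.asarray(coords), labels


def ligand_at_interface(model: StructureModel, interface: Interface,
                        ligand_cutoff: float = 5.0) -> list[LigandBinding]:
    """Ligands bound at the interface (any ligand atom < cutoff from any
    interface-residue atom); waters were already excluded at parse time."""
    iface_coords, labels = _interface_residue_atoms(model, interface)
    if len(iface_coords) == 0:
        return []
    tree = cKDTree(iface_coords)
    bindings: list[LigandBinding] = []
    for chain_id, lig in model.all_ligands():
        lig_coords = lig.coords()
        hits = tree.query_ball_point(lig_coords, r=ligand_cutoff)
        touched: set[tuple[str, ResidueKey]] = set()
        for atom_hits, lig_xyz in zip(hits, lig_coords):
            for idx in atom_hits:
                # strict "< cutoff"
                if np.linalg.norm(iface_coords[idx] - lig_xyz) < ligand_cutoff:
                    touched.add(labels[idx])
        if not touched:
            continue
        sides = {side for side, _ in touched}
        bindings.append(LigandBinding(
            ligand_code=lig.name,
            ligand_instance=(chain_id, lig.number, lig.icode),
            interface_id=interface.id,
            bound_side="both" if len(sides) == 2 else next(iter(sides)),
            contact_residues=frozenset(touched),
        ))
    return sorted(bindings, key=lambda b: (b.ligand_code, b.ligand_instance))


def filter_fda_ligands(bindings: Sequence[LigandBinding],
                       fda_codes: set[str],
                       excluded: frozenset[str] = EXCLUDED_CRYO_ADDITIVES
                       ) -> list[LigandBinding]:
    """Keep bindings of approved drugs, minus cryoprotectant artefacts.

    Glycerol (GOL) and isopropyl alcohol (IPA) appear in the approved-drug
    list but are ubiquitous crystallography additives, so they are
    excluded.
    """
    if not fda_codes:
        logger.warning("filter_fda_ligands: empty FDA code set")
        return []
    allowed = set(fda_codes) - set(excluded)
    return [b for b in bindings if b.ligand_code in allowed]


def _fmt_keys(keys) -> str:
    return ",".join(f"{n}{i}" for n, i in sorted(keys))


def write_interface_table(interfaces: Sequence[Interface]) -> str:
    lines = ["interface_id\tentry\tchain_a\tchain_b\tresidues_a\tresidues_b\tn_contacts"]
    for f in sorted(interfaces, key=lambda f: f.id):
        lines.append(
            f"{f.id}\t{f.entry_id}\t{f.chain_a}\t{f.chain_b}\t"
            f"{_fmt_keys(f.residues_a)}\t{_fmt_keys(f.residues_b)}\t{len(f.contacts)}"
        )
    return "\n".join(lines) + "\n"


def write_binding_table(bindings: Sequence[LigandBinding]) -> str:
    lines = ["ligand_code\tinstance\tinterface_id\tbound_side\tcontact_residues"]
    for b in bindings:
        ch, num, ic = b.ligand_instance
        contacts = ";".join(
            f"{side}:{n}{i}" for side, (n, i) in sorted(b.contact_residues))
        lines.append(
            f"{b.ligand_code}\t{ch}{num}{ic}\t{b.interface_id}\t{b.bound_side}\t{contacts}"
        )
    return "\n".join(lines) + "\n"
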