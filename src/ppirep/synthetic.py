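"""Synthetic fixtures with planted ground truth for every pipeline stage.

Real inputs to this pipeline (PDB entries, STRING edges, COSMIC tables,
viability screens) require database downloads; the generators here build
miniature versions of each with the answer known by construction:

* two-chain complexes in which exactly ``n_contact_pairs`` residue pairs
  satisfy the vdW + 0.5 A contact rule, every other pair sitting at
  least 2 A beyond the threshold;
* ligands planted at controlled distances on or off an interface;
* conformer families (noisy copies vs hinge-displaced or mutated
  chains) with a known partition;
* interface-descriptor families with known cluster labels;
* mutation / residue-mapping / sensitivity / edge tables with planted
  positives.

Chains are poly-alanine C-alpha traces with idealized geometry: the
contact and similarity rules are purely geometric, so side chains add
nothing.  Every structural generator re-derives its planted truth with a
brute-force all-pairs contact scan before returning, so a fixture can
never disagree with its own label.  Identical seeds give byte-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conformers import ChainRecord
from .similarity import InterfaceDescriptor
from .structure import (Atom, Chain, Residue, StructureModel, VdwTable,
                        parse_structure, write_structure)

__all__ = [
    "ToyScenario",
    "make_complex",
    "plant_ligand",
    "make_conformer_family",
    "make_cluster_fixture",
    "make_tables",
    "make_docking_poses",
    "make_scenario",
    "brute_force_contacts",
]

_SPACING = 6.0       # A between residues along a chain axis
_CONTACT_GAP = 3.5   # A across the interface (C-C threshold is 3.90)
_FAR_GAP = 12.0      # A for non-contacting rows (>= 2 A beyond threshold)
_JITTER = 0.05       # A of seeded positional jitter

AA3 = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
       "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL")
_ONE = "ARNDCQEGHILKMFPSTWYV"


def brute_force_contacts(chain_a: Chain, chain_b: Chain, vdw: VdwTable,
                         tol: float = 0.5) -> set[tuple]:
    """All-pairs O(n^2) residue contact scan (the generator's own gate)."""
    found = set()
    for res_a in chain_a.residues:
        for res_b in chain_b.residues:
            hit = False
            for atom_a in res_a.atoms:
                for atom_b in res_b.atoms:
                    d = float(np.linalg.norm(atom_a.coord - atom_b.coord))
                    cut = vdw.radius(atom_a.element) + vdw.radius(atom_b.element) + tol
                    if d < cut:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                found.add((res_a.key, res_b.key))
    return found


def _ca_residue(number: int, coord: np.ndarray, name: str = "ALA") -> Residue:
    return Residue(name=name, number=number,
                   atoms=[Atom(name="CA", element="C", coord=coord)])


def make_complex(n_res_a: int = 30, n_res_b: int = 30,
                 n_contact_pairs: int = 6, seed: int = 0,
                 entry_id: str = "TOY1") -> tuple[str, dict]:
    """Two-chain complex with exactly ``n_contact_pairs`` contacting
    residue pairs; returns (PDB text, truth).

    Truth keys: ``entry_id``, ``chain_a``/``chain_b``, ``contacts`` (set
    of residue-key pairs), ``residues_a``/``residues_b``.
    """
    if n_contact_pairs > min(n_res_a, n_res_b):
        raise ValueError("n_contact_pairs exceeds chain length")
    rng = np.random.default_rng(seed)

    def jitter() -> np.ndarray:
        return rng.uniform(-_JITTER, _JITTER, size=3)

    coords_a = [np.array([i * _SPACING, 0.0, 0.0]) + jitter()
                for i in range(n_res_a)]
    coords_b = []
    for i in range(n_res_b):
        y = _CONTACT_GAP if i < n_contact_pairs else _FAR_GAP
        coords_b.append(np.array([i * _SPACING, y, 0.0]) + jitter())

    chain_a = Chain("A", [_ca_residue(i + 1, c) for i, c in enumerate(coords_a)])
    chain_b = Chain("B", [_ca_residue(i + 1, c) for i, c in enumerate(coords_b)])
    model = StructureModel(entry_id, [chain_a, chain_b])

    expected = {((i + 1, ""), (i + 1, "")) for i in range(n_contact_pairs)}
    actual = brute_force_contacts(chain_a, chain_b, VdwTable())
    if actual != expected:
        raise RuntimeError("synthetic complex failed its contact self-check")
    truth = {
        "entry_id": entry_id,
        "chain_a": "A",
        "chain_b": "B",
        "contacts": expected,
        "residues_a": {k for k, _ in expected},
        "residues_b": {k for _, k in expected},
        "ligands": [],
    }
    return write_structure(model), truth


def plant_ligand(pdb_text: str, truth: dict, at_interface: bool = True,
                 ligand_code: str = "LIG", distance: float = 4.0,
                 side: str = "a", seed: int = 0) -> tuple[str, dict]:
    """Place a one-atom ligand at a controlled distance from a residue.

    ``at_interface`` targets a planted contact residue (side "a", "b",
    or "both" for a bridging pose); otherwise a far non-interface
    residue.  The stated distance is exact to float precision; the
    geometry guarantees no other residue comes closer than
    sqrt(distance^2 + 3.4^2).
    """
    model = parse_structure(pdb_text, entry_id=truth["entry_id"])
    chain_a = model.chain(truth["chain_a"])
    chain_b = model.chain(truth["chain_b"])
    rng = np.random.default_rng(seed)
    contacts = sorted(truth["contacts"])
    if at_interface:
        if not contacts:
            raise ValueError("no planted contacts to target")
        key_a, key_b = contacts[rng.integers(len(contacts))]
        atom_a = next(r for r in chain_a.residues if r.key == key_a).atoms[0]
        atom_b = next(r for r in chain_b.residues if r.key == key_b).atoms[0]
        if side == "both":
            # equidistant bridge: raise out of plane until both gaps = distance
            mid = (atom_a.coord + atom_b.coord) / 2.0
            half = float(np.linalg.norm(atom_b.coord - atom_a.coord)) / 2.0
            if distance <= half:
                raise ValueError("bridge distance too small for the gap")
            height = float(np.sqrt(distance ** 2 - half ** 2))
            pos = mid + np.array([0.0, 0.0, height])
            expected = {("chain_a", key_a), ("chain_b", key_b)}
        else:
            target = atom_a if side == "a" else atom_b
            key = key_a if side == "a" else key_b
            pos = target.coord + np.array([0.0, 0.0, distance])
            expected = {(f"chain_{side}", key)}
        bound_side = "both" if side == "both" else f"chain_{side}"
    else:
        far = [r for r in chain_b.residues if r.key not in truth["residues_b"]]
        if not far:
            raise ValueError("every residue is at the interface")
        target = far[-1].atoms[0]
        pos = target.coord + np.array([0.0, 0.0, distance])
        expected = set()
        bound_side = None

    lig_chain = Chain("L")
    instance_number = 900 + len(truth["ligands"]) + 1
    lig_chain.ligands.append(Residue(
        name=ligand_code, number=instance_number, is_polymer=False,
        atoms=[Atom(name="C1", element="C", coord=pos)]))
    chains = [c for c in model.chains if c.id != "L"]
    existing = next((c for c in model.chains if c.id == "L"), None)
    if existing is not None:
        existing.ligands.extend(lig_chain.ligands)
        chains.append(existing)
    else:
        chains.append(lig_chain)
    new_model = StructureModel(model.entry_id, chains, model.source)
    truth = dict(truth)
    truth["ligands"] = list(truth["ligands"]) + [{
        "code": ligand_code,
        "instance": ("L", instance_number, ""),
        "at_interface": at_interface,
        "bound_side": bound_side,
        "contact_residues": expected,
        "distance": distance,
    }]
    return write_structure(new_model), truth


def _helix(n: int) -> np.ndarray:
    t = np.arange(n) * np.deg2rad(100.0)
    return np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)])


def _random_rigid(rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-20, 20, size=3)
    return coords @ rot.T + shift


def make_conformer_family(n_similar: int = 3, n_distinct: int = 2,
                          noise_rmsd: float = 0.5, seed: int = 0,
                          n_res: int = 60, accession: str = "P00001"
                          ) -> tuple[dict, list[set]]:
    """Chains of one accession with a known conformer partition.

    ``n_similar`` chains are noise-perturbed rigid copies of a base fold
    (pairwise RMSD well under 2 A, identity 1.0) and form one group;
    each of the ``n_distinct`` chains is either hinge-displaced (RMSD
    far above 2 A) or mutated below 95% identity, and is its own group.

    Returns ({accession: [ChainRecord, ...]}, truth partition as a list
    of sets of (entry_id, chain_id)).
    """
    rng = np.random.default_rng(seed)
    base = _helix(n_res)
    sequence = "".join(rng.choice(list(_ONE), size=n_res))
    records: list[ChainRecord] = []
    truth: list[set] = []

    similar = set()
    for i in range(n_similar):
        noisy = base + rng.normal(0.0, noise_rmsd / np.sqrt(3.0), size=base.shape)
        coords = _random_rigid(rng, noisy)
        key = (f"S{i:03d}", "A")
        records.append(ChainRecord(key[0], key[1], sequence, coords))
        similar.add(key)
    truth.append(similar)

    mut_positions = rng.permutation(n_res)
    used = 0
    for i in range(n_distinct):
        key = (f"D{i:03d}", "A")
        if i % 2 == 0:
            # hinge: swing the second half by a member-specific angle
            from scipy.spatial.transform import Rotation
            angle = 100.0 + 70.0 * (i // 2)
            half = n_res // 2
            coords = base.copy()
            pivot = coords[half]
            rot = Rotation.from_euler("x", angle, degrees=True).as_matrix()
            coords[half:] = (coords[half:] - pivot) @ rot.T + pivot
            records.append(ChainRecord(key[0], key[1], sequence,
                                       _random_rigid(rng, coords)))
        else:
            # mutate ~20% of positions (disjoint sets across members)
            n_mut = max(int(0.2 * n_res), int(0.06 * n_res) + 1)
            seq = list(sequence)
            for p in mut_positions[used:used + n_mut]:
                choices = [c for c in _ONE if c != seq[p]]
                seq[p] = choices[rng.integers(len(choices))]
            used += n_mut
            records.append(ChainRecord(key[0], key[1], "".join(seq),
                                       _random_rigid(rng, base)))
        truth.append({key})
    return {accession: records}, truth


def make_cluster_fixture(n_families: int = 3, members_per_family: int = 3,
                         seed: int = 0, n_per_side: int = 20
                         ) -> tuple[list[InterfaceDescriptor], list[set]]:
    """Interface descriptors in structurally similar families.

    Members of one family are rigid + small-noise copies of a family
    archetype; archetypes of different families are independent random
    geometries.  Returns (descriptors, truth label sets)."""
    rng = np.random.default_rng(seed)
    descriptors: list[InterfaceDescriptor] = []
    truth: list[set] = []
    for fam in range(n_families):
        side_a = rng.uniform(-8, 8, size=(n_per_side, 3))
        side_b = side_a + np.array([0.0, 0.0, 4.5]) + \
            rng.normal(0.0, 0.8, size=(n_per_side, 3))
        contacts = frozenset((i, i) for i in range(n_per_side))
        codes = [AA3[i] for i in rng.integers(0, 20, size=2 * n_per_side)]
        labels = set()
        for m in range(members_per_family):
            noise_a = rng.normal(0.0, 0.2, size=side_a.shape)
            noise_b = rng.normal(0.0, 0.2, size=side_b.shape)
            stacked = _random_rigid(rng, np.vstack([side_a + noise_a,
                                                    side_b + noise_b]))
            iface_id = f"FAM{fam}_M{m}_A_B"
            descriptors.append(InterfaceDescriptor(
                interface_id=iface_id,
                coords_a=stacked[:n_per_side],
                coords_b=stacked[n_per_side:],
                codes_a=codes[:n_per_side],
                codes_b=codes[n_per_side:],
                contacts=contacts,
            ))
            labels.add(iface_id)
        truth.append(labels)
    return descriptors, truth


def make_tables(truth: dict, seed: int = 0,
                n_interface_mutations: int = 3,
                n_off_mutations: int = 7,
                drugs: Sequence[str] = ("TPV", "MK1", "ROC"),
                n_cell_lines: int = 6,
                accession: str = "P10001") -> dict:
    """Mutation, mapping, sensitivity, FDA-code and edge tables with
    planted answers, keyed off a complex's truth record.

    Mutations are planted on chain-A residues: ``n_interface_mutations``
    on planted interface residues (the first carrying a deleterious SIFT
    score), the rest well off the interface.  The sensitivity table
    plants one incomplete cell line (missing the last drug) that
    complete-case handling must drop.
    """
    rng = np.random.default_rng(seed)
    iface_keys = sorted(truth["residues_a"])[:n_interface_mutations]
    if len(iface_keys) < n_interface_mutations:
        raise ValueError("not enough planted interface residues")
    max_iface = max(k[0] for k in truth["residues_a"])

    rows = ["accession\tseq_position\tref_aa\talt_aa\tmutation_type\t"
            "frequency\ttissues\tsift_score"]
    planted_iface, planted_off = [], []
    lig_contact_positions = set()
    for lig in truth.get("ligands", []):
        for side_label, key in lig["contact_residues"]:
            if side_label == "chain_a":
                lig_contact_positions.add(key[0])
    for idx, (num, _ic) in enumerate(iface_keys):
        sift = 0.01 if idx == 0 else round(float(rng.uniform(0.2, 0.9)), 2)
        freq = round(float(rng.uniform(1e-5, 1e-4)), 7)
        rows.append(f"{accession}\t{num}\tA\tV\tmissense\t{freq}\tlung\t{sift}")
        planted_iface.append(num)
    for j in range(n_off_mutations):
        num = max_iface + 3 + j  # beyond every interface residue
        freq = round(float(rng.uniform(1e-5, 1e-4)), 7)
        rows.append(f"{accession}\t{num}\tA\tG\tmissense\t{freq}\tskin\t")
        planted_off.append(num)
    mutation_tsv = "\n".join(rows) + "\n"

    map_rows = ["accession\tseq_position\tentry\tchain\tauth_number\ticode\taa"]
    n_res = max(planted_off) + 2
    for pos in range(1, n_res + 1):
        map_rows.append(
            f"{accession}\t{pos}\t{truth['entry_id']}\t{truth['chain_a']}\t{pos}\t\tA")
    mapping_tsv = "\n".join(map_rows) + "\n"

    drug_means = {d: round(float(rng.uniform(-1.5, 0.2)), 3) for d in drugs}
    sens_rows = ["cell_line,drug,value"]
    for c in range(n_cell_lines):
        line = f"CL{c + 1}"
        for k, drug in enumerate(drugs):
            if c == n_cell_lines - 1 and k == len(drugs) - 1:
                continue  # planted incomplete cell line
            value = drug_means[drug] + round(float(rng.normal(0.0, 0.1)), 4)
            sens_rows.append(f"{line},{drug},{value:.4f}")
    sensitivity_csv = "\n".join(sens_rows) + "\n"

    fda_codes = sorted(set(drugs) | {"GOL", "IPA", "GNT", "CWB"})
    edge_rows = ["acc_a\tacc_b\tscore",
                 "P1\tP2\t0.950", "P2\tP3\t0.900",
                 "P3\tP4\t0.899", "P1\tP4\t0.500"]
    edge_tsv = "\n".join(edge_rows) + "\n"

    return {
        "mutation_tsv": mutation_tsv,
        "mapping_tsv": mapping_tsv,
        "sensitivity_csv": sensitivity_csv,
        "fda_codes": fda_codes,
        "edge_tsv": edge_tsv,
        "truth": {
            "accession": accession,
            "interface_mutation_positions": planted_iface,
            "off_mutation_positions": planted_off,
            "deleterious_positions": planted_iface[:1],
            "ligand_contact_positions": sorted(
                lig_contact_positions & set(planted_iface)),
            "drug_means": drug_means,
            "incomplete_cell_line": f"CL{n_cell_lines}",
            "kept_edges": {("P1", "P2"), ("P2", "P3")},
        },
    }


def make_docking_poses(seed: int = 0):
    """Receptor patch plus a planted good-binder pose and a clashing pose.

    The good pose puts every ligand atom inside the attractive 3-5 A
    shell of several receptor atoms; the clash pose drives one atom to
    1 A.  Returns (receptor_coords, receptor_elems, good_pose,
    clash_pose, ligand_elems)."""
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(np.arange(4) * 3.0, np.arange(4) * 3.0)
    receptor = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(16)])
    receptor += rng.uniform(-0.05, 0.05, size=receptor.shape)
    good = np.array([[4.5, 4.5, 4.0], [6.0, 4.5, 4.0], [4.5, 6.0, 4.0]])
    clash = good.copy()
    clash[0] = receptor[5] + np.array([0.0, 0.0, 1.0])
    elems = ["C"] * len(receptor)
    return receptor, elems, good, clash, ["C", "C", "C"]


@dataclass
class ToyScenario:
    """A complete generated study: structures, tables, and their truth."""

    seed: int
    structures: dict[str, str]          # entry_id -> PDB text
    pathway_entries: set[str]           # entries whose interfaces are "pathway"
    complex_truth: dict[str, dict]      # entry_id -> make_complex/plant truth
    tables: dict = field(default_factory=dict)

    def manifest(self) -> str:
        def _default(obj):
            if isinstance(obj, (set, frozenset)):
                return sorted(obj, key=repr)
            if isinstance(obj, tuple):
                return list(obj)
            raise TypeError(type(obj).__name__)
        payload = {
            "seed": self.seed,
            "entries": sorted(self.structures),
            "pathway_entries": sorted(self.pathway_entries),
            "truth": self.complex_truth,
            "tables_truth": self.tables.get("truth", {}),
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_default)


def make_scenario(seed: int = 0) -> ToyScenario:
    """Assemble a full toy study for the end-to-end pipeline.

    Three two-chain complexes: PATH1 (a pathway entry with the drug GNT
    planted at its interface), DRUG1 (a structurally similar non-pathway
    complex with the drug TPV at its interface, plus a glycerol
    artefact), and FAR1 (an unrelated non-pathway complex).  PATH1 and
    DRUG1 interfaces share the same planted layout, so they co-cluster
    at the 0.311 threshold and drive both repurposing directions.
    """
    rng = np.random.default_rng(seed)
    structures: dict[str, str] = {}
    truths: dict[str, dict] = {}

    text, truth = make_complex(30, 30, 8, seed=int(rng.integers(2 ** 31)),
                               entry_id="PATH1")
    text, truth = plant_ligand(text, truth, at_interface=True,
                               ligand_code="GNT", distance=4.0, side="b",
                               seed=int(rng.integers(2 ** 31)))
    structures["PATH1"] = text
    truths["PATH1"] = truth

    # DRUG1 reuses PATH1's layout (same planted contacts) with fresh jitter
    text, truth = make_complex(30, 30, 8, seed=int(rng.integers(2 ** 31)),
                               entry_id="DRUG1")
    text, truth = plant_ligand(text, truth, at_interface=True,
                               ligand_code="TPV", distance=4.0, side="a",
                               seed=int(rng.integers(2 ** 31)))
    text, truth = plant_ligand(text, truth, at_interface=True,
                               ligand_code="GOL", distance=4.0, side="b",
                               seed=int(rng.integers(2 ** 31)))
    structures["DRUG1"] = text
    truths["DRUG1"] = truth

    # FAR1: different contact geometry so it lands in its own cluster
    far_seed = int(rng.integers(2 ** 31))
    far_rng = np.random.default_rng(far_seed)
    side_a = far_rng.uniform(-10, 10, size=(12, 3))
    side_b = side_a[::-1] + np.array([2.5, 1.5, 2.0])
    chain_a = Chain("A", [_ca_residue(i + 1, c) for i, c in enumerate(side_a)])
    chain_b = Chain("B", [_ca_residue(i + 1, c) for i, c in enumerate(side_b)])
    far_model = StructureModel("FAR1", [chain_a, chain_b])
    far_contacts = brute_force_contacts(chain_a, chain_b, VdwTable())
    structures["FAR1"] = write_structure(far_model)
    truths["FAR1"] = {
        "entry_id": "FAR1", "chain_a": "A", "chain_b": "B",
        "contacts": far_contacts,
        "residues_a": {k for k, _ in far_contacts},
        "residues_b": {k for _, k in far_contacts},
        "ligands": [],
    }

    scenario = ToyScenario(
        seed=seed,
        structures=structures,
        pathway_entries={"PATH1"},
        complex_truth=truths,
    )
    scenario.tables = make_tables(truths["PATH1"],
                                  seed=int(rng.integers(2 ** 31)))
    return scenario
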