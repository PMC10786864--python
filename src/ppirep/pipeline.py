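"""End-to-end toy pipeline: structures in, candidate tables out.

Runs every stage on a generated scenario: parse structures, drop short
chains, extract interfaces, map ligands, filter to approved drugs
(minus GOL/IPA artefacts), build descriptors, cluster at the similarity
threshold, apply both repurposing strategies, pose-transfer the drug
onto each proposed target by interface superposition, score with the
surrogate potential, and run the random-drug control.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from . import docking as dk
from . import interfaces as ifc
from . import repurposing as rp
from . import similarity as sim
from .structure import StructureModel, VdwTable, filter_short_chains, parse_structure
from .synthetic import ToyScenario, make_scenario

__all__ = ["PipelineResult", "run_pipeline", "run_toy_pipeline"]


@dataclass
class PipelineResult:
    scenario: ToyScenario
    models: dict[str, StructureModel]
    interfaces: dict[str, ifc.Interface]
    bindings: list[ifc.LigandBinding]
    drug_bindings: list[ifc.LigandBinding]
    clusters: list[sim.InterfaceCluster]
    candidates_to: list[rp.CandidatePair]
    candidates_from: list[rp.CandidatePair]
    scored: list[dk.ScoredPair]
    control: dk.ControlSummary
    tables: dict[str, str]


def _ligand_arrays(model: StructureModel, code: str):
    for _chain_id, lig in model.all_ligands():
        if lig.name == code:
            return lig.coords(), [a.element for a in lig.atoms]
    raise KeyError(f"{model.entry_id}: no ligand {code}")


def _receptor_arrays(model: StructureModel, interface: ifc.Interface):
    coords, elems = [], []
    for chain_id in (interface.chain_a, interface.chain_b):
        for res in model.chain(chain_id).residues:
            for atom in res.atoms:
                coords.append(atom.coord)
                elems.append(atom.element)
    return np.asarray(coords), elems


def _transfer_pose(source_desc, target_desc, ligand_coords):
    """Move a ligand from its source interface frame onto the target via
    the interface superposition (index correspondence, as in scoring)."""
    from .conformers import superpose_rmsd
    m_a = min(len(source_desc.coords_a), len(target_desc.coords_a))
    m_b = min(len(source_desc.coords_b), len(target_desc.coords_b))
    ref = np.vstack([target_desc.coords_a[:m_a], target_desc.coords_b[:m_b]])
    mov = np.vstack([source_desc.coords_a[:m_a], source_desc.coords_b[:m_b]])
    sup = superpose_rmsd(ref, mov)
    return (sup.rotation @ np.asarray(ligand_coords).T).T + sup.translation


def _control_scorer(models, interfaces, seed):
    """Deterministic stand-in poses for library drugs: a 3-atom rigid
    ligand dropped near the interface box centre, displacement fixed by
    a (drug, interface, seed) hash."""
    def scorer(drug: str, interface_id: str) -> float:
        interface = interfaces[interface_id]
        model = models[interface.entry_id]
        box = dk.docking_box(model, interface)
        key = zlib.crc32(f"{drug}|{interface_id}|{seed}".encode()) % (2 ** 31)
        rng = np.random.default_rng(key)
        base = np.asarray(box.center) + rng.uniform(-2.0, 2.0, size=3)
        lig = base + np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0]])
        rec_coords, rec_elems = _receptor_arrays(model, interface)
        return dk.surrogate_score(rec_coords, rec_elems, lig, ["C"] * 3)
    return scorer


def run_pipeline(scenario: ToyScenario,
                 threshold: float = sim.DEFAULT_THRESHOLD,
                 min_chain_len: int = 10,
                 control_n: int = 35) -> PipelineResult:
    """Run every stage on a scenario; returns all intermediate products.

    ``min_chain_len`` defaults below the real-data value of 30 because
    toy chains are short; the filter semantics are identical.
    """
    vdw = VdwTable()
    models = {
        entry: parse_structure(text, entry_id=entry)
        for entry, text in sorted(scenario.structures.items())
    }
    kept = filter_short_chains(list(models.values()), min_len=min_chain_len)
    models = {m.entry_id: m for m in kept}

    interfaces: dict[str, ifc.Interface] = {}
    bindings: list[ifc.LigandBinding] = []
    for entry in sorted(models):
        model = models[entry]
        for interface in ifc.enumerate_interfaces(model, vdw):
            interfaces[interface.id] = interface
            bindings.extend(ifc.ligand_at_interface(model, interface))

    fda_codes = set(scenario.tables.get("fda_codes", []))
    drug_bindings = ifc.filter_fda_ligands(bindings, fda_codes)

    descriptors = {
        iface_id: sim.descriptor_from_interface(models[interface.entry_id],
                                                interface)
        for iface_id, interface in interfaces.items()
    }
    clusters = sim.cluster_interfaces(list(descriptors.values()),
                                      threshold=threshold)

    pathway_ifaces = {i for i in interfaces
                     if interfaces[i].entry_id in scenario.pathway_entries}
    candidates_to = rp.repurpose_to(clusters, drug_bindings, pathway_ifaces)
    candidates_from = rp.repurpose_from(clusters, drug_bindings, pathway_ifaces)

    binding_by = {(b.ligand_code, b.interface_id): b for b in drug_bindings}
    scored: list[dk.ScoredPair] = []
    for pair in candidates_to + candidates_from:
        source = next(s for s in pair.sources
                      if (pair.drug, s) in binding_by)
        target_iface = interfaces[pair.target_interface]
        target_model = models[target_iface.entry_id]
        lig_coords, lig_elems = _ligand_arrays(
            models[interfaces[source].entry_id], pair.drug)
        pose = _transfer_pose(descriptors[source],
                              descriptors[pair.target_interface], lig_coords)
        rec_coords, rec_elems = _receptor_arrays(target_model, target_iface)
        energy = dk.surrogate_score(rec_coords, rec_elems, pose, lig_elems)
        # receptor label: the side contributing more close approaches
        d = np.linalg.norm(rec_coords[:, None, :] - pose[None, :, :], axis=2)
        n_a_atoms = sum(len(r.atoms) for r in
                        target_model.chain(target_iface.chain_a).residues)
        close = d.min(axis=1) < 5.0
        receptor_chain = (target_iface.chain_a
                          if close[:n_a_atoms].sum() >= close[n_a_atoms:].sum()
                          else target_iface.chain_b)
        scored.append(dk.ScoredPair(candidate=pair,
                                    receptor_chain=receptor_chain,
                                    delta_g=energy, engine="surrogate"))

    library = sorted(set(scenario.tables.get("fda_codes", [])) |
                     {f"Z{i:03d}" for i in range(40)})
    target_ifaces = sorted({p.target_interface
                            for p in candidates_to + candidates_from}) \
        or sorted(interfaces)
    control = dk.control_set_stats(
        library, target_ifaces,
        _control_scorer(models, interfaces, scenario.seed),
        n=control_n, seed=scenario.seed)

    tables = {
        "interfaces.tsv": ifc.write_interface_table(list(interfaces.values())),
        "bindings.tsv": ifc.write_binding_table(drug_bindings),
        "clusters.tsv": sim.write_cluster_table(clusters),
        "candidates.tsv": rp.write_candidate_table(
            candidates_to + candidates_from),
        "scores.tsv": _score_table(scored),
    }
    return PipelineResult(
        scenario=scenario, models=models, interfaces=interfaces,
        bindings=bindings, drug_bindings=drug_bindings, clusters=clusters,
        candidates_to=candidates_to, candidates_from=candidates_from,
        scored=scored, control=control, tables=tables,
    )


def _score_table(scored) -> str:
    lines = ["drug\ttarget_interface\tdirection\treceptor_chain\tdelta_g\tengine"]
    for s in sorted(scored, key=lambda s: (s.delta_g, s.candidate.drug,
                                           s.candidate.target_interface)):
        lines.append(
            f"{s.candidate.drug}\t{s.candidate.target_interface}\t"
            f"{s.candidate.direction}\t{s.receptor_chain}\t{s.delta_g:.4f}\t{s.engine}")
    return "\n".join(lines) + "\n"


def run_toy_pipeline(seed: int = 0, **kwargs) -> PipelineResult:
    """Generate a scenario from ``seed`` and run the full pipeline."""
    return run_pipeline(make_scenario(seed), **kwargs)
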