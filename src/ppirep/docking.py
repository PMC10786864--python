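"""Docking-box construction, binding-energy scoring, candidate selection.

Candidates surviving the cluster-based pairing are ranked by predicted
binding free energy inside a box centred on the interface.  Scoring is
pluggable:

* ``external`` shells out to an AutoDock-Vina-compatible executable
  (exhaustiveness 8 by default) and reads the best-pose energy in
  kcal/mol.
* ``surrogate`` is a deterministic distance-binned pair potential
  (attractive well at 3-5 A, clash penalty below 2.5 A) over receptor-
  ligand heavy-atom pairs, on a kcal/mol-like scale.  It exists so the
  pipeline is exercisable end to end without an engine; its numbers are
  *not* comparable to Vina energies and only orderings are meaningful.

Selection keeps candidates at or below an energy cutoff (default
-7.3 kcal/mol).  A control set of randomly drawn approved drugs scored
against the same interfaces calibrates what "unremarkable" binding looks
like.
"""

from __future__ import annotations

import shutil
import statistics
import subprocess
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .interfaces import Interface
from .repurposing import CandidatePair, region_filter
from .structure import StructureModel

__all__ = [
    "DockingBox",
    "ScoredPair",
    "ControlSummary",
    "docking_box",
    "surrogate_score",
    "score_binding",
    "select_candidates",
    "control_set_stats",
]

DEFAULT_ENERGY_CUTOFF = -7.3  # kcal/mol
DEFAULT_EXHAUSTIVENESS = 8
DEFAULT_PADDING = 4.0  # A per side

# surrogate potential bins (heavy atoms only)
_CLASH_DIST = 2.5
_WELL_LO, _WELL_HI = 3.0, 5.0
_NEIGHBOR_CUTOFF = 8.0
_WELL_ENERGY = -0.18   # kcal/mol per well pair
_CLASH_ENERGY = 1.5    # kcal/mol per A of overlap


@dataclass(frozen=True)
class DockingBox:
    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError("box sizes must be positive")

    def contains(self, point: np.ndarray) -> bool:
        c = np.asarray(self.center)
        half = np.asarray(self.size) / 2.0
        return bool(np.all(np.abs(np.asarray(point) - c) <= half + 1e-9))


@dataclass(frozen=True)
class ScoredPair:
    candidate: CandidatePair
    receptor_chain: str
    delta_g: float  # kcal/mol
    engine: str  # "external" | "surrogate"

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")


@dataclass(frozen=True)
class ControlSummary:
    n_drugs: int
    drugs: tuple[str, ...]
    energies: tuple[float, ...]
    mean: float
    median: float
    sd: float


def docking_box(model: StructureModel, interface: Interface,
                padding: float = DEFAULT_PADDING) -> DockingBox:
    """Axis-aligned box covering every atom of both sides' interface
    residues, with ``padding`` added on each face."""
    coords = []
    for chain_id, keys in ((interface.chain_a, interface.residues_a),
                           (interface.chain_b, interface.residues_b)):
        chain = model.chain(chain_id)
        for res in chain.residues:
            if res.key in keys:
                coords.extend(a.coord for a in res.atoms)
    if not coords:
        raise ValueError(f"{interface.id}: no interface-residue atoms")
    xyz = np.asarray(coords)
    lo = xyz.min(axis=0)
    hi = xyz.max(axis=0)
    center = (lo + hi) / 2.0
    size = (hi - lo) + 2.0 * padding
    box = DockingBox(center=tuple(center), size=tuple(size))
    assert all(box.contains(p) for p in xyz)
    return box


def _heavy_coords(coords: np.ndarray, elements: Sequence[str]) -> np.ndarray:
    mask = [e.upper() != "H" for e in elements]
    return np.asarray(coords, dtype=float)[mask]


def surrogate_score(receptor_coords: np.ndarray,
                    receptor_elements: Sequence[str],
                    ligand_coords: np.ndarray,
                    ligand_elements: Sequence[str]) -> float:
    """Deterministic binned pair potential, kcal/mol-like.

    Pairs in the 3-5 A well contribute a fixed attraction; pairs closer
    than 2.5 A contribute a linear clash penalty.  A ligand with no
    receptor atom within 8 A scores exactly 0.  Depends only on pairwise
    distances, hence rigid-transform invariant.
    """
    rec = _heavy_coords(receptor_coords, receptor_elements)
    lig = _heavy_coords(ligand_coords, ligand_elements)
    if len(rec) == 0 or len(lig) == 0:
        return 0.0
    d = np.linalg.norm(rec[:, None, :] - lig[None, :, :], axis=2)
    if not np.any(d < _NEIGHBOR_CUTOFF):
        return 0.0
    well = np.sum((d >= _WELL_LO) & (d <= _WELL_HI))
    clash_overlap = np.sum(np.clip(_CLASH_DIST - d, 0.0, None))
    return float(well * _WELL_ENERGY + clash_overlap * _CLASH_ENERGY)


def _run_external(engine_config: Mapping, box: DockingBox) -> float:
    exe = engine_config.get("executable", "vina")
    if shutil.which(exe) is None:
        raise RuntimeError(
            f"docking engine {exe!r} not found on PATH; external scoring "
            "requires an installed engine (no silent fallback)")
    prepare = engine_config.get("prepare_hook")
    if prepare is None:
        raise RuntimeError("external engine requires a 'prepare_hook' that "
                           "writes receptor/ligand input files")
    receptor_file, ligand_file = prepare()
    cx, cy, cz = box.center
    sx, sy, sz = box.size
    cmd = [
        exe,
        "--receptor", str(receptor_file), "--ligand", str(ligand_file),
        "--center_x", f"{cx:.3f}", "--center_y", f"{cy:.3f}",
        "--center_z", f"{cz:.3f}",
        "--size_x", f"{sx:.3f}", "--size_y", f"{sy:.3f}", "--size_z", f"{sz:.3f}",
        "--exhaustiveness",
        str(engine_config.get("exhaustiveness", DEFAULT_EXHAUSTIVENESS)),
    ]
    out = subprocess.run(cmd, capture_output=True, text=True, check=True).stdout
    for line in out.splitlines():
        parts = line.split()
        if len(parts) >= 2 and parts[0] == "1":
            return float(parts[1])
    raise RuntimeError("could not parse best-pose energy from engine output")


def score_binding(receptor_coords: np.ndarray,
                  receptor_elements: Sequence[str],
                  ligand_coords: np.ndarray,
                  ligand_elements: Sequence[str],
                  box: DockingBox,
                  engine: str = "surrogate",
                  engine_config: Mapping | None = None) -> float:
    """Predicted binding energy (kcal/mol) of a ligand pose."""
    if engine == "surrogate":
        return surrogate_score(receptor_coords, receptor_elements,
                               ligand_coords, ligand_elements)
    if engine == "external":
        return _run_external(engine_config or {}, box)
    raise ValueError(f"unknown engine {engine!r}")


def select_candidates(scored: Sequence[ScoredPair],
                      cutoff: float = DEFAULT_ENERGY_CUTOFF,
                      interface_region: Mapping[str, str] | None = None
                      ) -> list[ScoredPair]:
    """Energy-cutoff selection: keep delta_g <= cutoff, drop candidates
    crossing the membrane (region filter), sort best-first."""
    passing = [s for s in scored if s.delta_g <= cutoff]
    if interface_region is not None:
        allowed = {p.candidate for p in region_filter(
            [s.candidate for s in passing], interface_region)}
        passing = [s for s in passing if s.candidate in allowed]
    return sorted(passing, key=lambda s: (s.delta_g, s.candidate.drug,
                                          s.candidate.target_interface))


def control_set_stats(drug_library: Sequence[str], interfaces: Sequence[str],
                      scorer: Callable[[str, str], float],
                      n: int = 35, seed: int = 0) -> ControlSummary:
    """Score a random control set of approved drugs against interfaces.

    Draws ``n`` drugs uniformly without replacement (seed-reproducible),
    scores every drug against every interface, and summarizes the pooled
    energies.
    """
    library = sorted(set(drug_library))
    if len(library) < n:
        raise ValueError(f"library has {len(library)} drugs, need {n}")
    rng = np.random.default_rng(seed)
    sample = tuple(sorted(rng.choice(library, size=n, replace=False)))
    energies = tuple(float(scorer(drug, iface))
                     for drug in sample for iface in interfaces)
    if not energies:
        raise ValueError("no interfaces to score against")
    return ControlSummary(
        n_drugs=n,
        drugs=sample,
        energies=energies,
        mean=statistics.fmean(energies),
        median=statistics.median(energies),
        sd=statistics.stdev(energies) if len(energies) > 1 else 0.0,
    )
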