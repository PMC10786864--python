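"""PPI network accounting and the two cluster-based repurposing strategies.

The pathway's protein-protein interaction network comes from a
STRING-style edge list filtered at high confidence (>= 0.900).  Each
protein may have several alternative conformations, so one network edge
expands into n_u x n_v conformer pairs that could in principle be
modelled; coverage statistics report how many edges have at least one
realized structure.

Candidate drug-target pairs come from structurally-similar-interface
clusters:

* Repurposing To   - a drug seen bound at any interface of a cluster is
  proposed for pathway interfaces in the same cluster.
* Repurposing From - a drug seen bound at a pathway interface is
  proposed for non-pathway interfaces in the same cluster.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import networkx as nx
import pandas as pd

from .similarity import InterfaceCluster

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "CandidatePair",
    "build_network",
    "enumerate_conformer_pairs",
    "coverage_stats",
    "repurpose_to",
    "repurpose_from",
    "region_filter",
    "write_candidate_table",
]


@dataclass
class PPINetwork:
    graph: nx.Graph  # nodes: accessions; node attrs: conformers, in_pathway
    min_confidence: float

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def conformers(self, accession: str) -> int:
        return self.graph.nodes[accession].get("conformers", 1)


@dataclass(frozen=True)
class CandidatePair:
    """A proposed (drug, target interface) pair.

    Identity is (drug, target); several source interfaces may support the
    same candidate and are kept as provenance.
    """

    drug: str
    target_interface: str
    direction: str  # "to" | "from"
    cluster_id: int
    sources: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.direction not in ("to", "from"):
            raise ValueError("direction must be 'to' or 'from'")
        if self.target_interface in self.sources and len(self.sources) == 1:
            raise ValueError("source and target interface must differ")

    @property
    def source_interface(self) -> str:
        return self.sources[0] if self.sources else ""


def build_network(edge_table: str | pd.DataFrame,
                  pathway_accessions: set[str],
                  min_confidence: float = 0.900,
                  conformer_counts: Mapping[str, int] | None = None
                  ) -> PPINetwork:
    """Build the network from a STRING-style TSV (acc_a, acc_b, score).

    A ``combined_score`` column on the STRING 0-1000 integer scale is
    accepted and normalized to [0, 1].  Edges below ``min_confidence``
    are dropped; duplicate undirected rows collapse to one edge.
    """
    if isinstance(edge_table, str):
        df = pd.read_csv(io.StringIO(edge_table), sep="\t")
    else:
        df = edge_table.copy()
    if "score" in df.columns:
        scores = df["score"].astype(float)
    elif "combined_score" in df.columns:
        scores = df["combined_score"].astype(float)
        if scores.max() > 1.0:
            scores = scores / 1000.0
    else:
        raise ValueError("edge table needs a 'score' or 'combined_score' column")
    graph = nx.Graph()
    for (a, b), score in zip(df.iloc[:, :2].itertuples(index=False), scores):
        if score < min_confidence:
            continue
        u, v = sorted((str(a), str(b)))
        prev = graph.get_edge_data(u, v)
        if prev is None or score > prev["confidence"]:
            graph.add_edge(u, v, confidence=float(score))
    counts = conformer_counts or {}
    known = set(graph.nodes)
    for acc in pathway_accessions - known:
        logger.warning("build_network: pathway accession %s absent from edges", acc)
    for node in graph.nodes:
        graph.nodes[node]["in_pathway"] = node in pathway_accessions
        graph.nodes[node]["conformers"] = int(counts.get(node, 1))
    return PPINetwork(graph=graph, min_confidence=min_confidence)


def enumerate_conformer_pairs(network: PPINetwork
                              ) -> tuple[int, dict[tuple[str, str], int]]:
    """Theoretical conformer-resolved interaction count per edge and total.

    A hetero edge (u, v) with n_u and n_v conformations yields n_u * n_v
    pairs; a self edge yields the unordered pairs with repetition,
    n (n + 1) / 2.
    """
    per_edge: dict[tuple[str, str], int] = {}
    for u, v in network.graph.edges:
        n_u = network.conformers(u)
        n_v = network.conformers(v)
        if n_u < 1 or n_v < 1:
            raise ValueError(f"conformer counts must be >= 1 on edge ({u}, {v})")
        if u == v:
            count = n_u * (n_u + 1) // 2
        else:
            count = n_u * n_v
        per_edge[tuple(sorted((u, v)))] = count
    return sum(per_edge.values()), per_edge


class CoverageStats(NamedTuple):
    covered: int
    total: int
    percent: int


def coverage_stats(network: PPINetwork,
                   realized_edges: set[tuple[str, str]]) -> CoverageStats:
    """Structural coverage of network edges, percent to integer precision."""
    all_edges = set(network.edges)
    realized = {tuple(sorted(e)) for e in realized_edges}
    if not realized <= all_edges:
        raise ValueError("realized edges must be a subset of network edges")
    total = len(all_edges)
    if total == 0:
        raise ValueError("network has no edges")
    covered = len(realized)
    return CoverageStats(covered, total, round(100.0 * covered / total))


def _candidates(clusters: Sequence[InterfaceCluster],
                drug_sources: Mapping[str, set[str]],
                target_pool: set[str],
                direction: str) -> list[CandidatePair]:
    by_key: dict[tuple[str, str], dict] = {}
    for cluster in clusters:
        for drug, bound in sorted(drug_sources.items()):
            sources = sorted(bound & cluster.members)
            if not sources:
                continue
            for target in sorted(target_pool & cluster.members):
                if target in sources:
                    continue
                key = (drug, target)
                entry = by_key.setdefault(
                    key, {"cluster_id": cluster.cluster_id, "sources": []})
                for s in sources:
                    if s not in entry["sources"]:
                        entry["sources"].append(s)
    return [
        CandidatePair(drug=drug, target_interface=target, direction=direction,
                      cluster_id=entry["cluster_id"],
                      sources=tuple(entry["sources"]))
        for (drug, target), entry in sorted(by_key.items())
    ]


def _group_bindings(bindings) -> dict[str, set[str]]:
    """drug code -> set of interface ids where it is observed bound."""
    grouped: dict[str, set[str]] = {}
    for b in bindings:
        grouped.setdefault(b.ligand_code, set()).add(b.interface_id)
    return grouped


def repurpose_to(clusters: Sequence[InterfaceCluster], bindings,
                 pathway_interfaces: set[str]) -> list[CandidatePair]:
    """Drugs bound anywhere in a cluster, proposed for the cluster's
    pathway interfaces."""
    return _candidates(clusters, _group_bindings(bindings),
                       pathway_interfaces, "to")


def repurpose_from(clusters: Sequence[InterfaceCluster], pathway_bindings,
                   pathway_interfaces: set[str]) -> list[CandidatePair]:
    """Drugs bound at pathway interfaces, proposed for the cluster's
    non-pathway interfaces."""
    grouped = {
        drug: {i for i in sources if i in pathway_interfaces}
        for drug, sources in _group_bindings(pathway_bindings).items()
    }
    grouped = {d: s for d, s in grouped.items() if s}
    all_members = set().union(*(c.members for c in clusters)) if clusters else set()
    targets = all_members - pathway_interfaces
    return _candidates(clusters, grouped, targets, "from")


def region_filter(pairs: Sequence[CandidatePair],
                  interface_region: Mapping[str, str]) -> list[CandidatePair]:
    """Drop pairs whose drug-bound source and proposed target sit on
    opposite sides of the membrane (intracellular vs extracellular); a
    transmembrane or unannotated interface passes with a warning."""
    opposite = {frozenset({"intracellular", "extracellular"})}
    kept = []
    for pair in pairs:
        target_region = interface_region.get(pair.target_interface)
        if target_region is None:
            logger.warning("region_filter: %s unannotated, retained",
                           pair.target_interface)
            kept.append(pair)
            continue
        clash = False
        for source in pair.sources:
            source_region = interface_region.get(source)
            if source_region is None:
                logger.warning("region_filter: %s unannotated", source)
                continue
            if frozenset({source_region, target_region}) in opposite:
                clash = True
                break
        if not clash:
            kept.append(pair)
    return kept


def write_candidate_table(pairs: Sequence[CandidatePair]) -> str:
    lines = ["drug\ttarget_interface\tdirection\tcluster_id\tsource_interfaces"]
    for p in sorted(pairs, key=lambda p: (p.direction, p.drug, p.target_interface)):
        lines.append(
            f"{p.drug}\t{p.target_interface}\t{p.direction}\t{p.cluster_id}\t"
            f"{','.join(p.sources)}"
        )
    return "\n".join(lines) + "\n"
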