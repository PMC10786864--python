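"""Grouping alternative conformations of the same protein.

Structure databases are redundant: one protein is typically deposited
many times, in near-identical conformations.  Chains of the same
accession are grouped when they share at least 95% global sequence
identity and superpose within 2 A C-alpha RMSD; one representative is
kept per group.  Groups are connected components of the pairwise link
graph (single linkage), which is deterministic and order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

__all__ = [
    "ChainRecord",
    "ConformerGroup",
    "SuperposeResult",
    "global_identity",
    "align_pair",
    "superpose_rmsd",
    "group_conformations",
    "pick_representative",
    "write_group_table",
]


class ChainRecord(NamedTuple):
    """One deposited chain of a protein accession."""

    entry_id: str
    chain_id: str
    sequence: str
    ca_coords: np.ndarray  # (n_res, 3)


@dataclass(frozen=True)
class ConformerGroup:
    accession: str
    members: frozenset[tuple[str, str]]  # (entry_id, chain_id)
    representative: tuple[str, str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("conformer group must be non-empty")
        if self.representative not in self.members:
            raise ValueError("representative must be a group member")


def _aligner() -> Align.PairwiseAligner:
    # global alignment, match +1 / mismatch 0, affine gaps -10 / -0.5
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_pair(seq_a: str, seq_b: str) -> tuple[float, list[tuple[int, int]]]:
    """Globally align two sequences.

    Returns the fractional identity (identical columns over alignment
    length, gap columns included in the denominator) and the list of
    aligned index pairs at identical positions.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(seq_a, seq_b)[0]
    identical: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if seq_a[i] == seq_b[j]:
                identical.append((i, j))
    return len(identical) / alignment.length, identical


def global_identity(seq_a: str, seq_b: str) -> float:
    """Global sequence identity in [0, 1]; symmetric."""
    identity, _ = align_pair(seq_a, seq_b)
    return identity


@dataclass
class SuperposeResult:
    rmsd: float
    rotation: np.ndarray  # (3, 3), proper (det +1)
    translation: np.ndarray  # (3,)
    degenerate: bool = False  # collinear / rank-deficient point set


def superpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperposeResult:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Classic Kabsch solution via the SVD-based rotation fit; the returned
    transform maps b into a's frame: ``R @ b + t ~= a``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    ac = a - cen_a
    bc = b - cen_b
    degenerate = min(np.linalg.matrix_rank(ac, tol=1e-8),
                     np.linalg.matrix_rank(bc, tol=1e-8)) < 2
    import warnings
    with warnings.catch_warnings():
        # degeneracy is detected above and reported via the result flag
        warnings.filterwarnings("ignore", message="Optimal rotation is not")
        rot, rssd = Rotation.align_vectors(ac, bc)
    matrix = rot.as_matrix()
    translation = cen_a - matrix @ cen_b
    return SuperposeResult(
        rmsd=float(rssd) / np.sqrt(n),
        rotation=matrix,
        translation=translation,
        degenerate=degenerate,
    )


def _linked(rec_a: ChainRecord, rec_b: ChainRecord, id_thresh: float,
            rmsd_thresh: float, min_aligned: int) -> bool:
    identity, pairs = align_pair(rec_a.sequence, rec_b.sequence)
    if identity < id_thresh or len(pairs) < min_aligned:
        return False
    ia, ib = zip(*pairs)
    result = superpose_rmsd(rec_a.ca_coords[list(ia)], rec_b.ca_coords[list(ib)])
    return result.rmsd <= rmsd_thresh


def group_conformations(
    chains: Mapping[str, Sequence[ChainRecord]],
    id_thresh: float = 0.95,
    rmsd_thresh: float = 2.0,
    min_aligned: int = 20,
) -> list[ConformerGroup]:
    """Partition each accession's chains into alternative-conformation groups.

    Two chains are linked iff global identity >= ``id_thresh`` AND the
    C-alpha RMSD over aligned identical positions is <= ``rmsd_thresh``
    (with at least ``min_aligned`` such positions, so structures covering
    disjoint parts of a protein are not spuriously merged).  Groups are
    the connected components of this link graph.
    """
    groups: list[ConformerGroup] = []
    for accession in sorted(chains):
        records = list(chains[accession])
        if not records:
            logger.info("group_conformations: accession %s has no chains",
                        accession)
            continue
        graph = nx.Graph()
        keys = [(r.entry_id, r.chain_id) for r in records]
        graph.add_nodes_from(keys)
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                if _linked(records[i], records[j], id_thresh, rmsd_thresh,
                           min_aligned):
                    graph.add_edge(keys[i], keys[j])
        meta = {k: len(r.sequence) for k, r in zip(keys, records)}
        for component in nx.connected_components(graph):
            members = frozenset(component)
            groups.append(ConformerGroup(
                accession=accession,
                members=members,
                representative=pick_representative(members, meta),
            ))
    return groups


def pick_representative(members: Iterable[tuple[str, str]],
                        chain_lengths: Mapping[tuple[str, str], int]
                        ) -> tuple[str, str]:
    """Deterministic representative: most resolved residues, then
    lexicographically smallest (entry_id, chain_id)."""
    members = list(members)
    if not members:
        raise ValueError("empty group")
    return min(members, key=lambda m: (-chain_lengths.get(m, 0), m))


def write_group_table(groups: Sequence[ConformerGroup]) -> str:
    """TSV: accession, group_index, entry_id, chain_id, is_representative."""
    lines = ["accession\tgroup_index\tentry_id\tchain_id\tis_representative"]
    index = 0
    for group in sorted(groups, key=lambda g: (g.accession, min(g.members))):
        for entry_id, chain_id in sorted(group.members):
            rep = int((entry_id, chain_id) == group.representative)
            lines.append(f"{group.accession}\t{index}\t{entry_id}\t{chain_id}\t{rep}")
        index += 1
    return "\n".join(lines) + "\n"
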