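"""Interface structural similarity scoring and clustering.

Interfaces from unrelated proteins can share the same architecture, and
that observation is what allows a drug bound at one interface to be
proposed for another.  Similarity here is an interface-similarity (IS)
style score in [0, 1]: the two interfaces are rigidly superposed,
residues are matched by spatial proximity, and each match contributes a
distance-damped term weighted by how well the residue's cross-interface
contacts are conserved.  Structurally similar interfaces are then pooled
by average-linkage agglomerative clustering with a similarity threshold
(default 0.311).

An interface is an unordered pair of sides, so both side pairings
(A-A'/B-B' and A-B'/B-A') are scored and the better one is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .conformers import superpose_rmsd
from .interfaces import Interface
from .structure import StructureModel

__all__ = [
    "InterfaceDescriptor",
    "InterfaceCluster",
    "descriptor_from_interface",
    "interface_similarity",
    "cluster_interfaces",
    "read_cluster_table",
    "write_cluster_table",
]

DEFAULT_THRESHOLD = 0.311


@dataclass
class InterfaceDescriptor:
    """Geometry + contact topology of one interface.

    ``contacts`` holds (i, j) index pairs: residue i on side A contacts
    residue j on side B.  Coordinates are one representative (C-alpha)
    point per contacting residue, in the residue order of the sides.
    """

    interface_id: str
    coords_a: np.ndarray
    coords_b: np.ndarray
    codes_a: Sequence[str]
    codes_b: Sequence[str]
    contacts: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        self.coords_a = np.asarray(self.coords_a, dtype=float)
        self.coords_b = np.asarray(self.coords_b, dtype=float)
        if len(self.coords_a) != len(self.codes_a) or \
           len(self.coords_b) != len(self.codes_b):
            raise ValueError("coordinate and residue-code counts differ")

    @property
    def n_residues(self) -> int:
        return len(self.coords_a) + len(self.coords_b)


@dataclass(frozen=True)
class InterfaceCluster:
    cluster_id: int
    members: frozenset[str]
    threshold: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be non-empty")


def descriptor_from_interface(model: StructureModel,
                              interface: Interface) -> InterfaceDescriptor:
    """Build a descriptor from an extracted interface (C-alpha per residue,
    falling back to the residue's first atom)."""
    sides = []
    index_of: list[dict] = []
    for chain_id, keys in ((interface.chain_a, interface.residues_a),
                           (interface.chain_b, interface.residues_b)):
        chain = model.chain(chain_id)
        coords, codes, lookup = [], [], {}
        for res in sorted((r for r in chain.residues if r.key in keys),
                          key=lambda r: r.key):
            atom = res.atom("CA") or res.atoms[0]
            lookup[res.key] = len(coords)
            coords.append(atom.coord)
            codes.append(res.name)
        sides.append((np.asarray(coords), codes))
        index_of.append(lookup)
    contacts = frozenset(
        (index_of[0][c.residue_a], index_of[1][c.residue_b])
        for c in interface.contacts
    )
    return InterfaceDescriptor(
        interface_id=interface.id,
        coords_a=sides[0][0], coords_b=sides[1][0],
        codes_a=sides[0][1], codes_b=sides[1][1],
        contacts=contacts,
    )


def _d0(n_min: int) -> float:
    return max(0.5, 1.24 * np.cbrt(n_min - 15.0) - 1.8)


def _neighbor_map(contacts: frozenset[tuple[int, int]], side: str) -> dict[int, set[int]]:
    nbr: dict[int, set[int]] = {}
    for i, j in contacts:
        if side == "a":
            nbr.setdefault(i, set()).add(j)
        else:
            nbr.setdefault(j, set()).add(i)
    return nbr


def _greedy_match(pa: np.ndarray, pb: np.ndarray, cutoff: float
                  ) -> list[tuple[int, int, float]]:
    """One-to-one nearest-neighbour assignment, closest pairs first."""
    if len(pa) == 0 or len(pb) == 0:
        return []
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for i, j in order:
        if d[i, j] > cutoff:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(int(i))
        used_b.add(int(j))
        matches.append((int(i), int(j), float(d[i, j])))
    return matches


def _score_pairing(a: InterfaceDescriptor, b: InterfaceDescriptor,
                   swapped: bool) -> float:
    b_sides = (b.coords_b, b.coords_a) if swapped else (b.coords_a, b.coords_b)
    b_contacts = frozenset((j, i) for i, j in b.contacts) if swapped else b.contacts

    # superpose on an index-wise correspondence (per side, up to the
    # shorter length), then match residues by proximity
    corr_a, corr_b = [], []
    for pa, pb in ((a.coords_a, b_sides[0]), (a.coords_b, b_sides[1])):
        m = min(len(pa), len(pb))
        corr_a.append(pa[:m])
        corr_b.append(pb[:m])
    ref = np.vstack(corr_a)
    mov = np.vstack(corr_b)
    if len(ref) < 3:
        return 0.0
    sup = superpose_rmsd(ref, mov)
    moved = [(sup.rotation @ side.T).T + sup.translation for side in b_sides]

    n_min = min(a.n_residues, b.n_residues)
    d0 = _d0(n_min)
    nbr_a = (_neighbor_map(a.contacts, "a"), _neighbor_map(a.contacts, "b"))
    nbr_b = (_neighbor_map(b_contacts, "a"), _neighbor_map(b_contacts, "b"))

    matches = [
        _greedy_match(a.coords_a, moved[0], 2.0 * d0),
        _greedy_match(a.coords_b, moved[1], 2.0 * d0),
    ]
    partner = [dict((i, j) for i, j, _ in m) for m in matches]

    total = 0.0
    for side, other in ((0, 1), (1, 0)):
        for i, j, dist in matches[side]:
            na = nbr_a[side].get(i, set())
            nb = nbr_b[side].get(j, set())
            # contact conservation: neighbours of i whose matched partner
            # is a neighbour of j
            shared = sum(1 for k in na if partner[other].get(k) in nb)
            f = (1.0 + shared) / (1.0 + max(len(na), len(nb)))
            total += f / (1.0 + (dist / d0) ** 2)
    return total / n_min


def interface_similarity(a: InterfaceDescriptor,
                         b: InterfaceDescriptor) -> float:
    """IS-style similarity score in [0, 1]; symmetric, rigid-invariant."""
    for d in (a, b):
        if len(d.coords_a) < 5 or len(d.coords_b) < 5:
            raise ValueError(
                f"{d.interface_id}: descriptors need >= 5 residues per side")
    return max(_score_pairing(a, b, swapped=False),
               _score_pairing(a, b, swapped=True))


def cluster_interfaces(descriptors: Sequence[InterfaceDescriptor],
                       threshold: float = DEFAULT_THRESHOLD,
                       method: str = "average") -> list[InterfaceCluster]:
    """Agglomerative clustering on distance 1 - similarity, cut so merged
    clusters have average similarity >= ``threshold``.

    Deterministic under input reordering: descriptors are processed in
    interface_id order and cluster ids are assigned by smallest member.
    """
    if not descriptors:
        raise ValueError("need at least one descriptor")
    ordered = sorted(descriptors, key=lambda d: d.interface_id)
    ids = [d.interface_id for d in ordered]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate interface ids")
    if len(ordered) == 1:
        return [InterfaceCluster(0, frozenset(ids), threshold)]
    n = len(ordered)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - interface_similarity(
                ordered[i], ordered[j])
    z = scipy_linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(z, t=1.0 - threshold, criterion="distance")
    by_label: dict[int, set[str]] = {}
    for label, iface_id in zip(labels, ids):
        by_label.setdefault(int(label), set()).add(iface_id)
    clusters = sorted(by_label.values(), key=min)
    return [InterfaceCluster(k, frozenset(members), threshold)
            for k, members in enumerate(clusters)]


def write_cluster_table(clusters: Sequence[InterfaceCluster]) -> str:
    lines = ["cluster_id\tinterface_id"]
    for cluster in sorted(clusters, key=lambda c: c.cluster_id):
        for iface_id in sorted(cluster.members):
            lines.append(f"{cluster.cluster_id}\t{iface_id}")
    return "\n".join(lines) + "\n"


def read_cluster_table(text: str,
                       threshold: float = DEFAULT_THRESHOLD
                       ) -> list[InterfaceCluster]:
    """Parse a cluster TSV; enforces the partition invariant."""
    members: dict[int, set[str]] = {}
    seen: dict[str, int] = {}
    lines = text.strip().splitlines()
    start = 1 if lines and lines[0].startswith("cluster_id") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 2 tab-separated fields")
        try:
            cluster_id = int(parts[0])
        except ValueError:
            raise ValueError(f"line {lineno}: bad cluster id {parts[0]!r}") from None
        iface_id = parts[1].strip()
        if not iface_id:
            raise ValueError(f"line {lineno}: empty interface id")
        if iface_id in seen and seen[iface_id] != cluster_id:
            raise ValueError(
                f"line {lineno}: interface {iface_id} appears in clusters "
                f"{seen[iface_id]} and {cluster_id}")
        seen[iface_id] = cluster_id
        members.setdefault(cluster_id, set()).add(iface_id)
    return [InterfaceCluster(cid, frozenset(m), threshold)
            for cid, m in sorted(members.items())]
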