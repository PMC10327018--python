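"""Consensus cell typing by Ward co-clustering across hemispheres.

The operational cell-type definition: a cell type is a group of neurons that
is more similar to a group of neurons in another brain than to any other
cell in the same brain.  Algorithmically, neurons from all hemispheres are
co-clustered with Ward linkage and the smallest dendrogram clusters are
extracted that (1) contain neurons from every required hemisphere and
(2) have approximately equal hemisphere counts (max/min ratio bounded by a
balance tolerance).  "Smallest possible" is formalised as assigning every
leaf to its deepest admissible ancestor, which yields a laminar partition
and degenerates correctly when the root is the only admissible node.

Admissibility alone over-splits: within a true type, the neurons of the
three hemispheres are statistically interchangeable, so the subtree readily
contains balanced cross-hemisphere triplets that pass both criteria.  Two
guards stand in for the manual review the criteria otherwise require.
First, an admissible node only becomes a cluster *candidate* if it is
clearly separated from its surroundings: the merge height of its parent
must exceed ``split_gap`` (default 2) times its own merge height, in the
spirit of dynamic tree cutting -- a proposed split must be supported by an
abrupt change in cluster distance, not by rearranging interchangeable
neurons.  Second, each emitted cluster is validated against the definition
itself: it stands only if every member is strictly closer to some
cross-hemisphere member of its own cluster than to any same-hemisphere cell
outside it; failures (including exact ties, as between indistinguishable
neurons) are dissolved upward into the next candidate ancestor.
"""

from __future__ import annotations

import itertools
import string
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .morphology import ScoreMatrix

__all__ = [
    "Dendrogram",
    "ConsensusCriteria",
    "ConsensusPartition",
    "MappingReport",
    "ward_linkage",
    "extract_consensus_clusters",
    "classify_mapping",
]


@dataclass
class Dendrogram:
    """Ward merge tree over hemisphere-tagged leaves (scipy linkage encoding).

    ``distances`` optionally keeps the pairwise distances the tree was built
    from; the cluster-definition check during extraction needs them.
    """

    Z: np.ndarray
    leaf_ids: list[str]
    leaf_tags: list[str]  # hemisphere per leaf
    distances: np.ndarray | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def node_leaves(self) -> list[list[int]]:
        """Leaf index sets for every node (leaves first, then merges)."""
        n = self.n_leaves
        sets: list[list[int]] = [[i] for i in range(n)]
        for a, b, *_ in self.Z:
            sets.append(sets[int(a)] + sets[int(b)])
        return sets


@dataclass
class ConsensusCriteria:
    """Admissibility rules for a consensus cluster.

    ``required_hemispheres`` defaults to every hemisphere present among the
    leaves; dropping a hemisphere from the requirement emulates types absent
    from a truncated volume.  ``balance_tolerance`` bounds the ratio of the
    largest to the smallest hemisphere count within a cluster ("approximately
    equal"); the default of 3 deliberately lets small clusters like {1, 1, 2}
    pass, since types with fewer neurons are the least variable.
    """

    required_hemispheres: frozenset | None = None
    balance_tolerance: float = 3.0
    min_per_hemisphere: int = 1

    def __post_init__(self):
        if self.balance_tolerance < 1:
            raise ValueError("balance_tolerance must be >= 1")

    def admissible(self, counts: Counter, required) -> bool:
        req_counts = [counts.get(h, 0) for h in required]
        if min(req_counts) < self.min_per_hemisphere:
            return False
        return max(req_counts) / min(req_counts) <= self.balance_tolerance

    def near_boundary(self, counts: Counter, required, margin: float = 0.1) -> bool:
        """Flag clusters whose balance ratio sits within ``margin`` of tolerance."""
        req_counts = [counts.get(h, 0) for h in required]
        if min(req_counts) == 0:
            return False
        ratio = max(req_counts) / min(req_counts)
        return ratio <= self.balance_tolerance < ratio * (1.0 + margin)


@dataclass
class ConsensusPartition:
    """Laminar assignment of all leaves into consensus clusters."""

    clusters: list[dict]  # {label, members: {hemisphere: [ids]}, flagged}
    unassigned: list[str] = field(default_factory=list)

    def labels(self) -> dict[str, str]:
        out = {}
        for c in self.clusters:
            for ids in c["members"].values():
                for nid in ids:
                    out[nid] = c["label"]
        for nid in self.unassigned:
            out[nid] = f"unassigned:{nid}"
        return out

    def n_clusters(self) -> int:
        return len(self.clusters)


def ward_linkage(dist: ScoreMatrix, hemisphere_tags: dict[str, str]) -> Dendrogram:
    """Ward minimum-variance agglomeration of a symmetric distance matrix."""
    V = dist.values
    if np.isnan(V).any():
        raise ValueError("NaN distances")
    if dist.row_ids != dist.col_ids:
        raise ValueError("distance matrix must be square with matching ids")
    Z = linkage(squareform(V, checks=False), method="ward")
    return Dendrogram(
        Z=Z,
        leaf_ids=list(dist.row_ids),
        leaf_tags=[hemisphere_tags[i] for i in dist.row_ids],
        distances=V.copy(),
    )


def _cluster_supported(
    members: list[int], D: np.ndarray, tags: list[str], tie_tol: float
) -> bool:
    """Definition check: every member strictly closer to a cross-hemisphere
    member of the cluster than to any same-hemisphere cell outside it.

    Differences below ``tie_tol`` (a fraction of the typical inter-neuron
    distance) count as ties and fail the check -- a same-hemisphere
    competitor outside the cluster that is not discernibly further than the
    nearest cross-hemisphere clustermate means the cluster is not a robust
    type.  A cluster with no same-hemisphere outsiders passes trivially.
    """
    mem = set(members)
    n = len(tags)
    for i in members:
        inside_cross = [D[i, j] for j in members if j != i and tags[j] != tags[i]]
        if not inside_cross:
            return False
        outside_same = [
            D[i, k] for k in range(n) if k not in mem and tags[k] == tags[i]
        ]
        if outside_same and min(inside_cross) >= min(outside_same) - tie_tol:
            return False
    return True


def extract_consensus_clusters(
    dend: Dendrogram,
    criteria: ConsensusCriteria | None = None,
    definition_check: bool = True,
    split_gap: float | None = 2.0,
    tie_fraction: float = 0.05,
    zero_tol: float = 1e-9,
) -> ConsensusPartition:
    """Extract the smallest admissible clusters as the consensus partition.

    Every leaf is assigned to its deepest admissible candidate ancestor;
    such ancestors form a chain, so the result is a laminar partition.
    ``split_gap`` demands that a candidate's parent merge height exceed
    ``split_gap`` times its own merge height (``None`` disables the guard,
    leaving the bare deepest-admissible-ancestor rule).  With
    ``definition_check`` (the default), each candidate cluster is then
    validated against the cell-type definition and dissolved into the next
    candidate ancestor if any member has a same-hemisphere competitor
    outside the cluster at least as close (within ``tie_fraction`` of the
    median inter-neuron distance, the resolution below which neurons count
    as indistinguishable) as its nearest cross-hemisphere clustermate; this
    repeats until all clusters stand.  Leaves with no
    admissible (and supported) ancestor are reported as unassigned, not
    attached to a neighbouring cluster.
    """
    if criteria is None:
        criteria = ConsensusCriteria()
    n = dend.n_leaves
    if n == 0:
        raise ValueError("empty dendrogram")
    required = criteria.required_hemispheres or frozenset(dend.leaf_tags)
    leaf_sets = dend.node_leaves()
    counts = [Counter(dend.leaf_tags[i] for i in s) for s in leaf_sets]
    admissible = [criteria.admissible(c, required) for c in counts]
    children = {n + k: (int(a), int(b)) for k, (a, b, *_) in enumerate(dend.Z)}
    root = n + len(dend.Z) - 1 if len(dend.Z) else 0
    heights = [0.0] * n + [float(h) for h in dend.Z[:, 2]]

    # parent pointers for the separation guard and the push-up pass
    parent_of = {root: -1}
    for node, (a, b) in children.items():
        parent_of[a] = node
        parent_of[b] = node

    def is_candidate(node: int) -> bool:
        if not admissible[node]:
            return False
        if split_gap is None or node == root:
            return True
        hp = heights[parent_of[node]]
        if hp <= zero_tol:  # indistinguishable surroundings: nothing to split
            return False
        return hp >= split_gap * heights[node]

    candidate = [is_candidate(i) for i in range(n + len(dend.Z))]

    assigned_node = [-1] * n
    stack = [(root, -1)]
    while stack:
        node, current = stack.pop()
        if candidate[node]:
            current = node
        if node < n:
            assigned_node[node] = current
            continue
        a, b = children[node]
        stack.append((a, current))
        stack.append((b, current))

    if definition_check:
        if dend.distances is None:
            raise ValueError("definition_check requires Dendrogram.distances")
        D = dend.distances
        tags = dend.leaf_tags
        offdiag = D[np.triu_indices(n, k=1)] if n > 1 else np.zeros(1)
        tie_tol = tie_fraction * float(np.median(offdiag))
        # dissolve unsupported candidate clusters upward, deepest first
        while True:
            by_node: dict[int, list[int]] = {}
            for leaf, node in enumerate(assigned_node):
                if node != -1:
                    by_node.setdefault(node, []).append(leaf)
            dissolved = False
            # ascending node index = deepest merges first (leaves < early merges)
            for node in sorted(by_node):
                members = by_node[node]
                if node == root and len(members) == n:
                    continue  # everything in one cluster: trivially supported
                if not _cluster_supported(members, D, tags, tie_tol):
                    nxt = parent_of.get(node, -1)
                    while nxt != -1 and not candidate[nxt]:
                        nxt = parent_of.get(nxt, -1)
                    for leaf in members:
                        assigned_node[leaf] = nxt
                    dissolved = True
                    break
            if not dissolved:
                break

    clusters: list[dict] = []
    unassigned: list[str] = []
    by_node = {}
    for leaf, node in enumerate(assigned_node):
        if node == -1:
            unassigned.append(dend.leaf_ids[leaf])
        else:
            by_node.setdefault(node, []).append(leaf)
    for k, (node, leaves) in enumerate(sorted(by_node.items())):
        members: dict[str, list[str]] = {}
        for leaf in leaves:
            members.setdefault(dend.leaf_tags[leaf], []).append(dend.leaf_ids[leaf])
        cnt = Counter(dend.leaf_tags[i] for i in leaves)
        clusters.append(
            {
                "label": f"CC{k:04d}",
                "members": members,
                "flagged": criteria.near_boundary(cnt, required),
            }
        )
    part = ConsensusPartition(clusters=clusters, unassigned=unassigned)
    n_leaves_out = sum(
        len(ids) for c in part.clusters for ids in c["members"].values()
    ) + len(part.unassigned)
    assert n_leaves_out == n, "partition must cover every leaf exactly once"
    return part


@dataclass
class MappingReport:
    """Relation of consensus clusters to a reference typing."""

    relations: dict[str, str]  # consensus label -> relation
    new_labels: dict[str, str]  # consensus label -> grammar label
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.counts:
            c = Counter(self.relations.values())
            self.counts = dict(c)
            total = sum(c.values())
            self.fractions = {k: v / total for k, v in c.items()} if total else {}


RELATIONS = ("one_to_one", "split", "merge", "recombination")


def classify_mapping(
    partition: ConsensusPartition, reference_types: dict[str, str]
) -> MappingReport:
    """Classify each consensus cluster against a reference typing.

    On the bipartite incidence between consensus clusters and reference
    types (over neurons labelled in both), each connected component is
    classified: 1 cluster-1 type -> one_to_one; many clusters-1 type ->
    split (labels get lower-case letter suffixes, "PS090a"); 1 cluster-many
    types -> merge (comma-joined composite label, "SIP078,SIP080"); else
    recombination.  Neurons unlabelled in the reference are ignored.
    """
    labels = partition.labels()
    shared = [nid for nid in labels if nid in reference_types and not labels[nid].startswith("unassigned:")]
    if not shared:
        raise ValueError("consensus partition and reference typing share no neurons")
    G = nx.Graph()
    for nid in shared:
        c = ("cluster", labels[nid])
        t = ("type", reference_types[nid])
        G.add_edge(c, t)
    relations: dict[str, str] = {}
    new_labels: dict[str, str] = {}
    for comp in nx.connected_components(G):
        cl = sorted(x[1] for x in comp if x[0] == "cluster")
        ty = sorted(x[1] for x in comp if x[0] == "type")
        if len(cl) == 1 and len(ty) == 1:
            rel = "one_to_one"
            new_labels[cl[0]] = ty[0]
        elif len(cl) > 1 and len(ty) == 1:
            rel = "split"
            for letter, c in zip(_letters(), cl):
                new_labels[c] = f"{ty[0]}{letter}"
        elif len(cl) == 1 and len(ty) > 1:
            rel = "merge"
            new_labels[cl[0]] = ",".join(ty)
        else:
            rel = "recombination"
            comp_label = ",".join(ty)
            for letter, c in zip(_letters(), cl):
                new_labels[c] = f"{comp_label}{letter}"
        for c in cl:
            relations[c] = rel
    return MappingReport(relations=relations, new_labels=new_labels)


def _letters():
    """a, b, ..., z, aa, ab, ... suffix generator for split labels."""
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)
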