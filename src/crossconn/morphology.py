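"""Skeleton conditioning and morphological similarity.

The similarity core follows the NBLAST recipe: neurons are reduced to
"dotprops" (a point cloud with a unit tangent per point, estimated from the
k nearest neighbours), each query point is matched to its nearest target
point, and the pair is scored by distance and tangent alignment.  The
published log-odds scoring matrix is not reproduced here; the default kernel
is ``exp(-d / sigma) * |dot|`` with sigma = 3 um, which preserves the
algorithm's structure (nearest-neighbour search scored by distance and dot
product) and is pluggable should an empirical matrix be available.

Scores are query->target sums; symmetrised "mean" scores are (S + S^T) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .io_formats import Skeleton

__all__ = [
    "Dotprops",
    "ScoreMatrix",
    "prune_twigs",
    "resample",
    "make_dotprops",
    "mirror",
    "nblast_pair",
    "nblast_matrix",
    "mean_scores",
    "scores_to_distance",
    "elbow_groups",
]


@dataclass
class Dotprops:
    """Point cloud with one unit tangent vector per point (micrometres)."""

    points: np.ndarray
    tangents: np.ndarray
    neuron_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.tangents = np.asarray(self.tangents, dtype=float).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValueError("empty dotprops")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("tangents must be unit vectors")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ScoreMatrix:
    """q x t score (or distance) matrix with row/column ids."""

    values: np.ndarray
    row_ids: list
    col_ids: list
    direction: str = "forward"  # forward | mean

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("score matrix shape does not match ids")

    def row(self, rid) -> dict:
        i = self.row_ids.index(rid)
        return dict(zip(self.col_ids, self.values[i]))


# ---------------------------------------------------------------------------
# skeleton conditioning
# ---------------------------------------------------------------------------

def _children_map(skel: Skeleton) -> dict[int, list[int]]:
    children: dict[int, list[int]] = {int(n): [] for n in skel.node_ids}
    for nid, pid in zip(skel.node_ids.tolist(), skel.parent_ids.tolist()):
        if pid != -1:
            children[pid].append(nid)
    return children


def _subset(skel: Skeleton, keep_ids: set[int]) -> Skeleton:
    mask = np.array([int(n) in keep_ids for n in skel.node_ids])
    new_parents = skel.parent_ids.copy()
    return Skeleton(
        skel.node_ids[mask], new_parents[mask], skel.xyz[mask], skel.radius[mask]
    )


def prune_twigs(skel: Skeleton, max_len_um: float = 5.0) -> Skeleton:
    """Iteratively remove terminal twigs shorter than ``max_len_um``.

    A twig is the path from a leaf up to (excluding) the nearest branch
    point or the root.  Removal is repeated until a fixpoint; the root is
    never removed, so a bare chain can at worst collapse to its root.
    """
    if max_len_um <= 0:
        return skel.copy()
    skel = skel.copy()
    while True:
        if len(skel) <= 1:
            return skel
        children = _children_map(skel)
        parent = dict(zip(skel.node_ids.tolist(), skel.parent_ids.tolist()))
        pos = {int(n): i for i, n in enumerate(skel.node_ids)}
        root = skel.root
        leaves = [n for n, ch in children.items() if not ch and n != root]
        to_remove: set[int] = set()
        for leaf in leaves:
            path = [leaf]
            length = 0.0
            node = leaf
            while True:
                par = parent[node]
                if par == -1:
                    break
                length += float(
                    np.linalg.norm(skel.xyz[pos[node]] - skel.xyz[pos[par]])
                )
                if len(children[par]) > 1 or par == root:
                    break
                path.append(par)
                node = par
            if length < max_len_um:
                to_remove.update(path)
        if not to_remove:
            return skel
        skel = _subset(skel, {int(n) for n in skel.node_ids} - to_remove)


def _segments(skel: Skeleton) -> list[list[int]]:
    """Decompose the tree into paths between root/branch points and tips.

    Each segment runs from a leaf or branch point rootward up to (and
    including) the nearest branch point or the root.
    """
    children = _children_map(skel)
    parent = dict(zip(skel.node_ids.tolist(), skel.parent_ids.tolist()))
    root = skel.root
    stops = {n for n, ch in children.items() if len(ch) > 1} | {root}
    starts = [n for n, ch in children.items() if not ch] + [
        n for n in stops if n != root and parent[n] != -1
    ]
    segs = []
    for start in set(starts):
        if start == root:
            continue
        path = [start]
        node = start
        while True:
            par = parent[node]
            if par == -1:
                break
            path.append(par)
            if par in stops:
                break
            node = par
        if len(path) > 1:
            segs.append(path)
    return segs


def resample(skel: Skeleton, spacing_um: float) -> Skeleton:
    """Resample each branch to ~``spacing_um`` node spacing along the cable.

    Branch points, tips and the root are preserved; interior nodes are
    placed by linear interpolation along the original polyline, so the total
    cable length is conserved up to corner-cutting between samples.
    """
    if spacing_um <= 0:
        raise ValueError("spacing_um must be > 0")
    pos = {int(n): i for i, n in enumerate(skel.node_ids)}
    new_nodes: dict[int, tuple[float, float, float, float, int]] = {}
    root = skel.root
    new_nodes[root] = (*skel.xyz[pos[root]], skel.radius[pos[root]], -1)
    next_id = int(skel.node_ids.max()) + 1
    kept = {n for seg in _segments(skel) for n in (seg[0], seg[-1])} | {root}
    for seg in _segments(skel):
        # seg runs tipward->rootward; reverse so it runs root->tip
        path = seg[::-1]
        xyz = skel.xyz[[pos[n] for n in path]]
        rad = skel.radius[[pos[n] for n in path]]
        d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(d)])
        total = arc[-1]
        n_int = max(1, int(round(total / spacing_um)))
        samples = np.linspace(0.0, total, n_int + 1)
        sx = np.interp(samples, arc, xyz[:, 0])
        sy = np.interp(samples, arc, xyz[:, 1])
        sz = np.interp(samples, arc, xyz[:, 2])
        sr = np.interp(samples, arc, rad)
        anchor_start, anchor_end = path[0], path[-1]
        if anchor_start not in new_nodes:
            new_nodes[anchor_start] = (*skel.xyz[pos[anchor_start]],
                                       skel.radius[pos[anchor_start]], -2)
        prev = anchor_start
        for j in range(1, len(samples)):
            if j == len(samples) - 1:
                nid = anchor_end
                new_nodes[nid] = (*skel.xyz[pos[anchor_end]],
                                  skel.radius[pos[anchor_end]], prev)
            else:
                nid = next_id
                next_id += 1
                new_nodes[nid] = (sx[j], sy[j], sz[j], sr[j], prev)
            prev = nid
    if len(new_nodes) == 1:
        return Skeleton([root], [-1], [new_nodes[root][:3]], [new_nodes[root][3]])
    # fix orphaned anchors (-2 placeholder: segment start whose rootward
    # segment was processed later); their parent comes from that other segment
    ids, parents, coords, radii = [], [], [], []
    for nid, (x, y, z, r, par) in new_nodes.items():
        ids.append(nid)
        parents.append(par if par != -2 else -3)
        coords.append((x, y, z))
        radii.append(r)
    # any -3 leftover means the anchor's rootward link was never written;
    # that only happens for the root (par already -1) so treat as error guard
    parents = [p if p != -3 else -1 for p in parents]
    return Skeleton(ids, parents, coords, radii)


def make_dotprops(source, k_neighbors: int = 5, neuron_id: str = "") -> Dotprops:
    """Build dotprops: tangent = first principal direction of k nearest points.

    ``source`` is a :class:`Skeleton` or an (n, 3) point array.  Tangents are
    sign-free (only their line matters).  If fewer than ``k_neighbors`` points
    exist, all points are used with a warning.
    """
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    if isinstance(source, Skeleton):
        pts = source.xyz
        if not neuron_id:
            neuron_id = str(source.root)
    else:
        pts = np.asarray(source, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n == 0:
        raise ValueError("no points")
    k = min(k_neighbors, n)
    if k < k_neighbors:
        warnings.warn(f"only {n} points available, using all for tangent estimation")
    if n == 1:
        return Dotprops(pts, np.array([[1.0, 0.0, 0.0]]), neuron_id)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    tangents = np.empty_like(pts)
    for i in range(n):
        nb = pts[idx[i]]
        nb = nb - nb.mean(axis=0)
        cov = nb.T @ nb
        w, v = np.linalg.eigh(cov)
        tangents[i] = v[:, -1]
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    return Dotprops(pts, tangents / norms, neuron_id)


def mirror(points: np.ndarray, midline_x: float = 0.0) -> np.ndarray:
    """Mirror points across the sagittal plane x = midline_x (an involution)."""
    pts = np.asarray(points, dtype=float).copy()
    pts[..., 0] = 2.0 * midline_x - pts[..., 0]
    return pts


def mirror_dotprops(dp: Dotprops, midline_x: float = 0.0) -> Dotprops:
    t = dp.tangents.copy()
    t[:, 0] = -t[:, 0]  # tangent direction flips in x under the mirror
    return Dotprops(mirror(dp.points, midline_x), t, dp.neuron_id)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _default_kernel(d: np.ndarray, absdot: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-d / sigma) * absdot


def nblast_pair(
    query: Dotprops,
    target: Dotprops,
    sigma: float = 3.0,
    kernel: Callable[[np.ndarray, np.ndarray, float], np.ndarray] | None = None,
) -> float:
    """Asymmetric query->target similarity score.

    Each query point is paired with its single nearest target point; the
    pair contributes ``kernel(distance, |tangent dot|)``.  A self-comparison
    therefore scores exactly ``len(query)``.
    """
    if kernel is None:
        kernel = _default_kernel
    tree = cKDTree(target.points)
    d, idx = tree.query(query.points, k=1)
    absdot = np.abs(np.einsum("ij,ij->i", query.tangents, target.tangents[idx]))
    return float(np.sum(kernel(np.asarray(d), absdot, sigma)))


def nblast_matrix(
    queries: Sequence[Dotprops],
    targets: Sequence[Dotprops] | None = None,
    sigma: float = 3.0,
    kernel=None,
) -> ScoreMatrix:
    """All-by-all forward scores; rows are queries, columns targets."""
    if targets is None:
        targets = queries
    if kernel is None:
        kernel = _default_kernel
    trees = [cKDTree(t.points) for t in targets]
    values = np.empty((len(queries), len(targets)))
    for j, (t, tree) in enumerate(zip(targets, trees)):
        for i, q in enumerate(queries):
            d, idx = tree.query(q.points, k=1)
            absdot = np.abs(np.einsum("ij,ij->i", q.tangents, t.tangents[idx]))
            values[i, j] = np.sum(kernel(np.asarray(d), absdot, sigma))
    return ScoreMatrix(
        values,
        [q.neuron_id for q in queries],
        [t.neuron_id for t in targets],
        direction="forward",
    )


def mean_scores(S: ScoreMatrix) -> ScoreMatrix:
    """Symmetrise a square forward score matrix: (S + S^T) / 2."""
    if S.values.shape[0] != S.values.shape[1] or S.row_ids != S.col_ids:
        raise ValueError("mean_scores requires a square matrix with matching ids")
    sym = (S.values + S.values.T) / 2.0
    return ScoreMatrix(sym, S.row_ids, S.col_ids, direction="mean")


def scores_to_distance(S_mean: ScoreMatrix) -> ScoreMatrix:
    """Map mean scores to distances in [0, 1].

    Each entry is normalised by the geometric mean of the two self-scores,
    clipped to [0, 1]; distance = 1 - normalised score, zero diagonal.
    """
    V = S_mean.values
    if V.shape[0] != V.shape[1] or S_mean.row_ids != S_mean.col_ids:
        raise ValueError("scores_to_distance requires a square matrix")
    self_scores = np.diag(V)
    if np.any(self_scores <= 0):
        raise ValueError("non-positive self-score")
    norm = V / np.sqrt(np.outer(self_scores, self_scores))
    dist = 1.0 - np.clip(norm, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return ScoreMatrix(dist, S_mean.row_ids, S_mean.col_ids, direction="mean")


def elbow_groups(distance: ScoreMatrix | np.ndarray, ids=None) -> dict:
    """Flat morphology groups: Ward linkage cut at the most abrupt height gap.

    The dendrogram is cut between the two successive merge heights with the
    largest gap.  If all successive gaps are equal within 1e-9 there is no
    abrupt change and a single group is returned.  Fewer than 3 items also
    yield a single group (with a warning).
    """
    if isinstance(distance, ScoreMatrix):
        D = distance.values
        ids = distance.row_ids
    else:
        D = np.asarray(distance, dtype=float)
        if ids is None:
            ids = list(range(len(D)))
    n = len(D)
    if n < 3:
        warnings.warn("fewer than 3 items: single group")
        return {i: 1 for i in ids}
    Z = linkage(squareform(D, checks=False), method="ward")
    heights = Z[:, 2]
    gaps = np.diff(heights)
    if len(gaps) == 0 or gaps.max() - gaps.min() < 1e-9:
        return {i: 1 for i in ids}
    k = int(np.argmax(gaps))
    cut = (heights[k] + heights[k + 1]) / 2.0
    flat = fcluster(Z, t=cut, criterion="distance")
    return dict(zip(ids, flat.tolist()))
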