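"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately written from the textbook definition, not by
calling the code under test: exhaustive nearest-neighbour search, naive
Lance-Williams agglomeration, leaf-set enumeration for cluster extraction,
dense eigendecomposition for the participation ratio, and union-find for
bipartite component classification.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def nblast_bruteforce(q_pts, q_tan, t_pts, t_tan, sigma=3.0) -> float:
    """Exhaustive-search pair score: for every query point scan all targets."""
    total = 0.0
    for p, u in zip(q_pts, q_tan):
        d_best, dot_best = np.inf, 0.0
        for q, v in zip(t_pts, t_tan):
            d = float(np.linalg.norm(p - q))
            if d < d_best:
                d_best, dot_best = d, abs(float(np.dot(u, v)))
        total += np.exp(-d_best / sigma) * dot_best
    return total


def ward_lance_williams(D: np.ndarray):
    """Naive Ward agglomeration via the Lance-Williams recurrence.

    Returns (sorted merge heights, set of frozensets of merged leaf sets).
    """
    D = np.asarray(D, dtype=float).copy()
    n = len(D)
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    heights = []
    merged_sets = set()
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        (i, j), h = min(
            ((k, v) for k, v in dist.items() if k[0] in active and k[1] in active),
            key=lambda kv: kv[1],
        )
        heights.append(h)
        new = clusters[i] | clusters[j]
        merged_sets.add(new)
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dij = h
            d_new = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            dist[tuple(sorted((next_id, k)))] = d_new
        active -= {i, j}
        active.add(next_id)
        clusters[next_id] = new
        sizes[next_id] = ni + nj
        next_id += 1
    return sorted(heights), merged_sets


def linkage_leaf_sets(Z: np.ndarray, n: int):
    """All node leaf sets of a scipy linkage matrix (leaves then merges)."""
    sets = [frozenset([i]) for i in range(n)]
    for a, b, *_ in Z:
        sets.append(sets[int(a)] | sets[int(b)])
    return sets


def extraction_oracle(Z: np.ndarray, tags, balance_tolerance=3.0, min_per=1):
    """Deepest-admissible-ancestor assignment by leaf-set enumeration.

    For each leaf, enumerate every dendrogram node containing it, keep the
    admissible ones, and pick the one with the smallest leaf set (the
    admissible ancestors of a leaf are nested, so this is the deepest).
    """
    n = len(tags)
    sets = linkage_leaf_sets(Z, n)
    required = set(tags)

    def admissible(s):
        c = Counter(tags[i] for i in s)
        counts = [c.get(h, 0) for h in required]
        return min(counts) >= min_per and max(counts) / min(counts) <= balance_tolerance

    adm = [admissible(s) for s in sets]
    assignment = {}
    for leaf in range(n):
        containing = [k for k, s in enumerate(sets) if leaf in s and adm[k]]
        if not containing:
            assignment[leaf] = None
        else:
            assignment[leaf] = min(containing, key=lambda k: len(sets[k]))
    return assignment


def participation_ratio_spectral(W: np.ndarray) -> float:
    """Dimensionality via the eigenvalues of C = W W^T."""
    C = W @ W.T
    lam = np.linalg.eigvalsh(C)
    return float(lam.sum() ** 2 / np.sum(lam**2))


def bipartite_relations(cluster_of: dict, type_of: dict):
    """Union-find classification of cluster-type components.

    Returns {cluster: relation} with relations in
    {one_to_one, split, merge, recombination}.
    """
    parent = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    shared = [nid for nid in cluster_of if nid in type_of]
    for nid in shared:
        union(("c", cluster_of[nid]), ("t", type_of[nid]))
    comps = {}
    for nid in shared:
        comps.setdefault(find(("c", cluster_of[nid])), [set(), set()])
    for nid in shared:
        root = find(("c", cluster_of[nid]))
        comps[root][0].add(cluster_of[nid])
        comps[root][1].add(type_of[nid])
    rel = {}
    for clusters, types in comps.values():
        if len(clusters) == 1 and len(types) == 1:
            r = "one_to_one"
        elif len(clusters) > 1 and len(types) == 1:
            r = "split"
        elif len(clusters) == 1 and len(types) > 1:
            r = "merge"
        else:
            r = "recombination"
        for c in clusters:
            rel[c] = r
    return rel


def prune_oracle(skel, max_len):
    """Remove short terminal twigs one at a time until a fixpoint.

    Recomputes everything from scratch after each single-leaf removal,
    unlike the implementation's batched per-pass removal.
    """
    node_ids = [int(x) for x in skel.node_ids]
    parents = {int(n): int(p) for n, p in zip(skel.node_ids, skel.parent_ids)}
    xyz = {int(n): np.asarray(p, dtype=float) for n, p in zip(skel.node_ids, skel.xyz)}
    root = [n for n, p in parents.items() if p == -1][0]
    while True:
        children = {n: [] for n in node_ids}
        for n, p in parents.items():
            if p != -1:
                children[p].append(n)
        removed = False
        for leaf in [n for n in node_ids if not children[n] and n != root]:
            path = [leaf]
            length = 0.0
            node = leaf
            while True:
                par = parents[node]
                if par == -1:
                    break
                length += float(np.linalg.norm(xyz[node] - xyz[par]))
                if len(children[par]) > 1 or par == root:
                    break
                path.append(par)
                node = par
            if length < max_len:
                for n in path:
                    node_ids.remove(n)
                    del parents[n], xyz[n]
                removed = True
                break
        if not removed:
            return sorted(node_ids)
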