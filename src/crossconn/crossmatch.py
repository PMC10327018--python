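"""Candidate type matching and cross-dataset distance construction.

Morphology scores propose candidate types (all hits at or above the query's
90th score percentile); an automated mutual-best rule stands in for manual
review.  Connectivity profiles stack query neurons from all hemispheres into
a single matrix whose columns are the cell types cross-identified in every
hemisphere, split into an input-side and an output-side block; pairwise
cosine distances over those rows are the connectivity distances, optionally
summed with morphology distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_formats import EdgeTable
from .morphology import ScoreMatrix

__all__ = [
    "CandidateSet",
    "ConnectivityProfile",
    "candidate_matches",
    "assign_by_mutual_best",
    "connectivity_profiles",
    "cosine_distances",
    "combined_distances",
]


@dataclass
class CandidateSet:
    query_id: str
    candidates: list[tuple[str, float]]  # (type_id, score), descending score

    def best(self) -> str | None:
        return self.candidates[0][0] if self.candidates else None


@dataclass
class ConnectivityProfile:
    """Neurons x (input types | output types) synapse-count matrix."""

    matrix: np.ndarray
    row_ids: list[str]
    row_hemispheres: list[str]
    shared_types: list[str]

    @property
    def columns(self) -> list[str]:
        return [f"in:{t}" for t in self.shared_types] + [
            f"out:{t}" for t in self.shared_types
        ]


def candidate_matches(
    scores: dict | pd.Series,
    labels_target: dict,
    percentile: float = 90.0,
    query_id: str = "",
) -> CandidateSet:
    """Candidate types for one query from its score vector over labelled targets.

    Targets scoring at or above the query's ``percentile``-th score percentile
    are kept and aggregated to type level by the maximum member score.  The
    percentile is taken over the query's own score vector, which makes the
    rule scale-free.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) == 0 or (s == 0).all():
        warnings.warn(f"query {query_id!r}: all-zero scores, no candidates")
        return CandidateSet(query_id, [])
    cut = np.percentile(s.to_numpy(), percentile)
    kept = s[s >= cut]
    by_type: dict[str, float] = {}
    for tid, sc in kept.items():
        ty = labels_target.get(tid)
        if ty is None:
            continue
        by_type[ty] = max(by_type.get(ty, -np.inf), float(sc))
    cands = sorted(by_type.items(), key=lambda kv: (-kv[1], kv[0]))
    return CandidateSet(query_id, cands)


def assign_by_mutual_best(
    S_mean: ScoreMatrix,
    labels_target: dict,
    percentile: float = 90.0,
    tie_tol: float = 1e-9,
) -> dict[str, str | None]:
    """Automated candidate resolution by reciprocal best hits.

    A query is assigned to type T iff T is its best candidate by a clear
    margin (ties within ``tie_tol`` leave the query unassigned) and the
    query ranks among the top-k queries for T, where k is T's member count
    (a reciprocal-rank check mirroring mutual-best-hit matching).
    """
    V = S_mean.values
    assignments: dict[str, str | None] = {}
    # per-type column ranking of queries: score of query to type = max member score
    types = sorted(set(labels_target.values()))
    type_cols = {
        t: [j for j, cid in enumerate(S_mean.col_ids) if labels_target.get(cid) == t]
        for t in types
    }
    type_scores = {t: V[:, cols].max(axis=1) for t, cols in type_cols.items() if cols}
    for i, qid in enumerate(S_mean.row_ids):
        row = {cid: V[i, j] for j, cid in enumerate(S_mean.col_ids) if cid != qid}
        cs = candidate_matches(row, labels_target, percentile, query_id=qid)
        if not cs.candidates:
            assignments[qid] = None
            continue
        if len(cs.candidates) > 1 and cs.candidates[0][1] - cs.candidates[1][1] < tie_tol:
            assignments[qid] = None
            continue
        best = cs.candidates[0][0]
        member_ids = {S_mean.col_ids[j] for j in type_cols[best]}
        k = len(member_ids)
        col = type_scores[best]
        # rank among queries that are not themselves members of the type
        rivals = np.array(
            [col[r] for r, rid in enumerate(S_mean.row_ids) if rid not in member_ids]
        )
        rank = int(np.sum(rivals > col[i] + tie_tol))
        assignments[qid] = best if rank < k else None
    return assignments


def connectivity_profiles(
    edge_tables: dict[str, EdgeTable],
    type_labels: dict[str, dict[str, str]],
    shared_types: list[str],
    query_ids: dict[str, list[str]] | None = None,
) -> ConnectivityProfile:
    """Stack per-hemisphere neuron x shared-type connectivity matrices.

    For each query neuron the input block counts synapses received from each
    shared type and the output block synapses sent to each shared type; rows
    from all hemispheres are concatenated.  Raw synapse counts are used:
    cosine distance is invariant to per-row scaling, so raw versus
    input-normalised profiles are equivalent downstream.
    """
    if not shared_types:
        raise ValueError("no common label space: shared_types is empty")
    shared = list(shared_types)
    col_of = {t: j for j, t in enumerate(shared)}
    n_shared = len(shared)
    rows, row_ids, row_hemi = [], [], []
    for hemi, table in edge_tables.items():
        labels = type_labels[hemi]
        pair = table.aggregate_neuropils()
        ids = query_ids[hemi] if query_ids is not None else sorted(
            set(pair["pre_id"]) | set(pair["post_id"])
        )
        mat = pd.DataFrame(
            np.zeros((len(ids), 2 * n_shared)), index=ids, columns=range(2 * n_shared)
        )
        pre_t = pair["pre_id"].map(labels)
        post_t = pair["post_id"].map(labels)
        # input block: synapses received from each shared type
        rec = pair[pair["post_id"].isin(ids) & pre_t.isin(shared)]
        for post, pre_type, w in zip(rec["post_id"], pre_t[rec.index], rec["weight"]):
            mat.loc[post, col_of[pre_type]] += w
        # output block: synapses sent to each shared type
        snt = pair[pair["pre_id"].isin(ids) & post_t.isin(shared)]
        for pre, post_type, w in zip(snt["pre_id"], post_t[snt.index], snt["weight"]):
            mat.loc[pre, n_shared + col_of[post_type]] += w
        rows.append(mat.to_numpy())
        row_ids.extend(ids)
        row_hemi.extend([hemi] * len(ids))
    return ConnectivityProfile(np.vstack(rows), row_ids, row_hemi, shared)


def cosine_distances(profile: ConnectivityProfile) -> ScoreMatrix:
    """Pairwise cosine distances between profile rows; zero rows are excluded.

    d(i, j) = 1 - x_i.x_j / (|x_i| |x_j|); on non-negative counts the range
    is [0, 1].  Neurons with zero connectivity to every shared type carry no
    signal and are dropped with a warning rather than pinned at an arbitrary
    distance.
    """
    X = profile.matrix
    norms = np.linalg.norm(X, axis=1)
    keep = norms > 0
    if not keep.all():
        dropped = [profile.row_ids[i] for i in np.nonzero(~keep)[0]]
        warnings.warn(f"excluding {len(dropped)} zero-connectivity neurons: {dropped[:5]}")
    X = X[keep]
    ids = [i for i, k in zip(profile.row_ids, keep) if k]
    D = squareform(pdist(X, metric="cosine"))
    np.fill_diagonal(D, 0.0)
    return ScoreMatrix(D, ids, ids, direction="mean")


def combined_distances(
    conn_dist: ScoreMatrix,
    morph_dist: ScoreMatrix,
    weights: tuple[float, float] = (1.0, 1.0),
) -> ScoreMatrix:
    """Element-wise weighted sum of connectivity and morphology distances."""
    if conn_dist.row_ids != morph_dist.row_ids or conn_dist.col_ids != morph_dist.col_ids:
        raise ValueError("distance matrices must share row/column ids")
    V = weights[0] * conn_dist.values + weights[1] * morph_dist.values
    return ScoreMatrix(V, conn_dist.row_ids, conn_dist.col_ids, direction="mean")
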