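"""Edge-level stereotypy across hemispheres.

An "edge" is the set of connections between two cell types; its weight is
the number of unitary synapses.  Given type-level edge tables for two or
more hemispheres sharing a label space, this module measures: how likely an
edge observed at a given weight in a reference hemisphere is to be found in
the others (persistence curves and thresholds for the "strong edge"
heuristics), how well matched edge weights agree (conditional quantile
envelopes and log-weight Pearson correlations), and how similar the
type-level connectivity vectors are (cosine similarity).

Normalised weights express an edge as the fraction of the target type's
total input (a 10-synapse edge onto a type receiving 200 inputs is 5%),
which buffers differences in synaptic completion rate between datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io_formats import EdgeTable

__all__ = [
    "UNTYPED",
    "TypedEdgeTable",
    "PersistenceCurve",
    "aggregate_type_edges",
    "normalize_by_input",
    "persistence_curve",
    "persistence_threshold",
    "weight_conditional_quantiles",
    "stereotypy_summaries",
]

#: Reserved bucket for partners without a type label; only ever used in
#: normalisation denominators, never as an edge endpoint of interest.
UNTYPED = "UNTYPED"


@dataclass
class TypedEdgeTable:
    """Type-level directed edges for one hemisphere.

    ``df`` columns: pre_type, post_type, optionally neuropil, weight, and
    (after normalisation) norm_weight = fraction of the post type's total
    input.  When a neuropil column is present, an "edge" is identified by
    the (pre_type, post_type, neuropil) triple throughout the module;
    otherwise by the type pair.
    """

    df: pd.DataFrame
    hemisphere: str = ""

    @property
    def key_columns(self) -> list[str]:
        return (
            ["pre_type", "post_type", "neuropil"]
            if "neuropil" in self.df.columns
            else ["pre_type", "post_type"]
        )

    def typed_only(self) -> pd.DataFrame:
        d = self.df
        return d[(d["pre_type"] != UNTYPED) & (d["post_type"] != UNTYPED)]

    def edge_index(self) -> pd.DataFrame:
        return self.typed_only().set_index(self.key_columns)


def aggregate_type_edges(
    edges: EdgeTable,
    type_labels: dict[str, str],
    hemisphere: str = "",
    by_neuropil: bool = False,
    strip_side_suffix: bool = True,
) -> TypedEdgeTable:
    """Aggregate a neuron-level edge table to cell-type level.

    Weights sum over member pairs (and, unless ``by_neuropil``, over
    neuropils); partners without a label fall into the reserved UNTYPED
    bucket so that input totals (and hence normalised weights) remain
    correct.  With ``by_neuropil``, side suffixes (``_L``/``_R``) are
    stripped by default so that mirrored neuropils align across hemispheres.
    """
    if by_neuropil:
        pair = edges.df.copy()
        if strip_side_suffix:
            pair["neuropil"] = pair["neuropil"].str.replace(r"_[LR]$", "", regex=True)
        keys = ["pre_type", "post_type", "neuropil"]
    else:
        pair = edges.aggregate_neuropils()
        keys = ["pre_type", "post_type"]
    pair = pair.assign(
        pre_type=pair["pre_id"].map(lambda x: type_labels.get(x, UNTYPED)),
        post_type=pair["post_id"].map(lambda x: type_labels.get(x, UNTYPED)),
    )
    df = pair.groupby(keys, as_index=False).agg(weight=("weight", "sum"))
    return TypedEdgeTable(df=df, hemisphere=hemisphere)


def normalize_by_input(typed: TypedEdgeTable) -> TypedEdgeTable:
    """Add norm_weight = weight / total input of the post type.

    Totals include UNTYPED inputs, so normalised weights of typed edges sum
    to 1 minus the untyped input fraction.  Post types with zero total input
    cannot be normalised and are dropped with a warning.
    """
    df = typed.df.copy()
    totals = df.groupby("post_type")["weight"].sum()
    zero = totals[totals <= 0].index
    if len(zero):
        warnings.warn(f"dropping post types with zero total input: {list(zero)[:5]}")
        df = df[~df["post_type"].isin(zero)]
    df["norm_weight"] = df["weight"] / df["post_type"].map(totals)
    return TypedEdgeTable(df=df, hemisphere=typed.hemisphere)


def _default_bins(max_weight: float, mode: str) -> np.ndarray:
    """Per-value bins up to 30 synapses, log-spaced above (absolute mode);
    log-spaced throughout for normalised weights."""
    if mode == "abs":
        fine = np.arange(1.0, min(31.0, max_weight + 1.0))
        if max_weight > 30:
            coarse = np.geomspace(31.0, max_weight + 1.0, 8)
            return np.unique(np.concatenate([fine, coarse]))
        return np.append(fine, max_weight + 1.0)
    lo = 1e-4
    return np.geomspace(lo, max(max_weight * 1.001, lo * 10), 25)


@dataclass
class PersistenceCurve:
    """Per-weight-bin edge persistence for a reference hemisphere.

    ``per_hemisphere[h]`` is the fraction of reference edges in the bin also
    present (type-level weight >= 1) in hemisphere h; ``p_both``/``p_one``/
    ``p_neither`` summarise presence across all other hemispheres;
    ``cum_syn_frac`` is the fraction of reference synapses on edges weaker
    than the bin's lower edge.
    """

    bin_edges: np.ndarray
    bin_mean_weight: np.ndarray
    n: np.ndarray
    per_hemisphere: dict[str, np.ndarray]
    p_both: np.ndarray
    p_one: np.ndarray
    p_neither: np.ndarray
    cum_syn_frac: np.ndarray
    mode: str = "abs"
    reference: str = ""

    @property
    def p_any(self) -> np.ndarray:
        return self.p_both + self.p_one


def persistence_curve(
    tables: dict[str, TypedEdgeTable],
    reference: str,
    mode: str = "abs",
    bins: np.ndarray | None = None,
) -> PersistenceCurve:
    """Probability that a reference edge is found in the other hemispheres.

    Edge existence is a type-level weight of at least one synapse.  The
    curve is computed per weight bin (not cumulatively); the weight axis is
    the reference edge's absolute weight (``mode='abs'``) or its normalised
    input fraction (``mode='norm'``, requires prior normalisation).
    """
    if reference not in tables:
        raise ValueError(f"reference hemisphere {reference!r} not in tables")
    others = [h for h in tables if h != reference]
    if not others:
        raise ValueError("need at least one non-reference hemisphere")
    ref = tables[reference].typed_only()
    shared_types = set(ref["pre_type"]) | set(ref["post_type"])
    for h in others:
        t = tables[h].typed_only()
        shared_types &= set(t["pre_type"]) | set(t["post_type"])
    if not shared_types:
        raise ValueError("no shared types between hemispheres")
    col = "weight" if mode == "abs" else "norm_weight"
    if col not in ref.columns:
        raise ValueError("normalised persistence requires normalize_by_input first")
    w = ref[col].to_numpy(dtype=float)
    if bins is None:
        bins = _default_bins(w.max(), mode)
    keys = tables[reference].key_columns
    present = {}
    for h in others:
        idx = set(map(tuple, tables[h].typed_only()[keys].to_numpy()))
        present[h] = np.array([tuple(e) in idx for e in ref[keys].to_numpy()])
    n_present = np.sum(list(present.values()), axis=0)
    which = np.digitize(w, bins) - 1
    nb = len(bins) - 1
    n = np.zeros(nb, dtype=int)
    mean_w = np.full(nb, np.nan)
    per_h = {h: np.full(nb, np.nan) for h in others}
    p_both = np.full(nb, np.nan)
    p_one = np.full(nb, np.nan)
    p_neither = np.full(nb, np.nan)
    for b in range(nb):
        mask = which == b
        n[b] = int(mask.sum())
        if n[b] == 0:
            continue
        mean_w[b] = w[mask].mean()
        for h in others:
            per_h[h][b] = present[h][mask].mean()
        p_both[b] = (n_present[mask] == len(others)).mean()
        p_neither[b] = (n_present[mask] == 0).mean()
        p_one[b] = 1.0 - p_both[b] - p_neither[b]
    total_syn = ref["weight"].sum()
    cum = np.array(
        [ref.loc[w < lo, "weight"].sum() / total_syn for lo in bins[:-1]]
    )
    return PersistenceCurve(
        bin_edges=np.asarray(bins, dtype=float),
        bin_mean_weight=mean_w,
        n=n,
        per_hemisphere=per_h,
        p_both=p_both,
        p_one=p_one,
        p_neither=p_neither,
        cum_syn_frac=cum,
        mode=mode,
        reference=reference,
    )


#: Sentinel returned when a persistence level is never reached.
NOT_REACHED = None


def persistence_threshold(
    curve: PersistenceCurve, level: float, which: str = "any"
):
    """Smallest weight threshold above which persistence stays >= level.

    Scans the binned curve and applies a plateau rule: the returned
    threshold is the lower edge of the first bin from which persistence is
    >= ``level`` in every populated bin at or above it.  Returns None when
    the level is never reached.
    """
    if not (0.0 <= level < 1.0) and level != 0:
        raise ValueError("level must be in [0, 1)")
    if which == "any":
        p = curve.p_any
    elif which == "both":
        p = curve.p_both
    else:
        p = curve.per_hemisphere[which]
    ok = np.zeros(len(p), dtype=bool)
    holds = True
    for b in range(len(p) - 1, -1, -1):
        if curve.n[b] > 0 and not (p[b] >= level):
            holds = False
        ok[b] = holds
    for b in range(len(p)):
        if ok[b] and curve.n[b] > 0:
            return float(curve.bin_edges[b])
    return NOT_REACHED


def weight_conditional_quantiles(
    table_A: TypedEdgeTable,
    table_B: TypedEdgeTable,
    quantiles=(0.05, 0.25, 0.5, 0.75, 0.95),
    min_count: int = 20,
) -> pd.DataFrame:
    """Quantile envelope of B's weight conditioned on A's weight.

    Matched edges (same pre/post type, present in both) are grouped by their
    weight in A over the grid 1..w_max; weight values with fewer than
    ``min_count`` matches are merged with the next value up (with warning).
    Returns a frame indexed by A-weight bin with one column per quantile.
    """
    a = table_A.edge_index()["weight"]
    b = table_B.edge_index()["weight"]
    both = a.index.intersection(b.index)
    if len(both) == 0:
        raise ValueError("no matched edges")
    wa = a.loc[both].to_numpy(dtype=float)
    wb = b.loc[both].to_numpy(dtype=float)
    order = np.argsort(wa, kind="stable")
    wa, wb = wa[order], wb[order]
    rows = []
    merged_warning = False
    bucket_w: list[float] = []
    bucket_b: list[float] = []
    for w in np.unique(wa):
        sel = wb[wa == w]
        bucket_w.extend([w] * len(sel))
        bucket_b.extend(sel.tolist())
        if len(bucket_b) >= min_count:
            qs = np.quantile(bucket_b, quantiles)
            rows.append((float(np.mean(bucket_w)), len(bucket_b), *qs))
            bucket_w, bucket_b = [], []
        else:
            merged_warning = True
    if bucket_b:
        qs = np.quantile(bucket_b, quantiles)
        rows.append((float(np.mean(bucket_w)), len(bucket_b), *qs))
    if merged_warning:
        warnings.warn(f"weight values with < {min_count} matches merged upward")
    return pd.DataFrame(
        rows, columns=["weight_A", "n", *(f"q{int(q * 100):02d}" for q in quantiles)]
    ).set_index("weight_A")


def stereotypy_summaries(
    tables: dict[str, TypedEdgeTable],
    cell_counts: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """Pairwise hemisphere summaries: edge-weight correlation and cosine similarity.

    For each hemisphere pair: Pearson R of log10 weight over matched edges
    (weights span orders of magnitude, so the usual log-log scatter is
    summarised on the log scale), mean per-type cosine similarity of
    input+output connectivity vectors over shared types, and (optionally)
    Pearson R of per-type cell counts.  Pairs with fewer than 3 matched
    items omit the statistic (NaN).
    """
    hemis = list(tables)
    rows = []
    for i, ha in enumerate(hemis):
        for hb in hemis[i + 1 :]:
            a = tables[ha].edge_index()["weight"]
            b = tables[hb].edge_index()["weight"]
            both = a.index.intersection(b.index)
            if len(both) >= 3:
                r_w = pearsonr(np.log10(a.loc[both]), np.log10(b.loc[both]))[0]
            else:
                r_w = np.nan
            cos = _mean_type_cosine(tables[ha], tables[hb])
            if cell_counts is not None:
                ca, cb = cell_counts[ha], cell_counts[hb]
                common = sorted(set(ca) & set(cb))
                if len(common) >= 3:
                    ka = np.array([ca[t] for t in common], dtype=float)
                    kb = np.array([cb[t] for t in common], dtype=float)
                    r_c = pearsonr(ka, kb)[0] if ka.std() > 0 and kb.std() > 0 else np.nan
                else:
                    r_c = np.nan
            else:
                r_c = np.nan
            rows.append((ha, hb, len(both), r_w, cos, r_c))
    return pd.DataFrame(
        rows,
        columns=[
            "hemisphere_a",
            "hemisphere_b",
            "n_matched_edges",
            "pearson_r_log_weight",
            "mean_cosine_similarity",
            "pearson_r_cell_counts",
        ],
    )


def _mean_type_cosine(A: TypedEdgeTable, B: TypedEdgeTable) -> float:
    """Mean cosine similarity of per-type connectivity vectors over shared types."""
    da, db = A.typed_only(), B.typed_only()
    types = sorted(
        (set(da["pre_type"]) | set(da["post_type"]))
        & (set(db["pre_type"]) | set(db["post_type"]))
    )
    if not types:
        return np.nan
    col = {t: j for j, t in enumerate(types)}
    k = len(types)

    def vectors(d):
        M = np.zeros((k, 2 * k))
        for pre, post, w in d[["pre_type", "post_type", "weight"]].itertuples(index=False):
            if pre in col and post in col:
                M[col[post], col[pre]] += w  # inputs
                M[col[pre], k + col[post]] += w  # outputs
        return M

    Ma, Mb = vectors(da), vectors(db)
    na = np.linalg.norm(Ma, axis=1)
    nb = np.linalg.norm(Mb, axis=1)
    ok = (na > 0) & (nb > 0)
    if not ok.any():
        return np.nan
    sims = np.einsum("ij,ij->i", Ma[ok], Mb[ok]) / (na[ok] * nb[ok])
    return float(sims.mean())
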