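"""Kenyon-cell expansion-coding analyses.

Kenyon cells (KCs) sparsely sample the ~58 olfactory input channels
(antennal-lobe projection-neuron types, one per glomerulus) and re-code
odours in a high-dimensional space; global inhibition from the APL neuron
keeps the code sparse.  This module computes the observed number of input
channels per KC (K), synaptic budget fractions, excitation/inhibition
ratios, and the linear rate-model dimensionality sweep that predicts the
K maximising coding dimensionality.

Rate model: KC activity is h = W r, with r the N-channel input (zero mean,
identity covariance, marginalised analytically).  W is M x N with K entries
of 1 - alpha and N - K entries of -alpha per row, alpha = A / M with A = 100
a fixed constant, so total inhibition scales with the KC population.  The
covariance is C = W W^T and the dimensionality is the participation ratio

    dim(h) = (Tr C)^2 / Tr(C^2)  in [1, M].

The per-K dimensionality is a Monte-Carlo mean over seeded random draws of
the K-subset per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import EdgeTable

__all__ = [
    "KCModelParams",
    "observed_K",
    "build_weight_matrix",
    "dimensionality",
    "dimensionality_curve",
    "optimal_K",
    "budget_fraction",
    "ei_ratio",
]


@dataclass
class KCModelParams:
    """Rate-model parameters; ``alpha`` is derived as A / M on construction."""

    M: int  # number of KCs
    N: int  # number of input channels (glomeruli / ALPN types)
    A: float = 100.0  # inhibition constant; alpha = A / M
    realisations: int = 100
    seed: int = 0
    alpha: float = field(init=False)

    def __post_init__(self):
        if self.M < 1 or self.N < 1:
            raise ValueError("M and N must be >= 1")
        self.alpha = self.A / self.M


def observed_K(
    edges: EdgeTable,
    kc_ids,
    channel_of_source: dict[str, str],
    threshold: int = 0,
) -> tuple[dict[str, int], float]:
    """Distinct input channels per KC and the population mean.

    For each KC, K is the number of distinct channels (glomeruli) whose
    summed input weight exceeds ``threshold`` synapses; the default of 0
    counts non-thresholded connectivity.  KCs with no mapped inputs count
    with K = 0.
    """
    kc_ids = list(kc_ids)
    pair = edges.aggregate_neuropils()
    pair = pair[pair["post_id"].isin(set(kc_ids))]
    pair = pair[pair["pre_id"].isin(channel_of_source)]
    pair = pair.assign(channel=pair["pre_id"].map(channel_of_source))
    by_channel = pair.groupby(["post_id", "channel"])["weight"].sum()
    above = by_channel[by_channel > threshold]
    counts = above.groupby("post_id").size()
    per_cell = {kc: int(counts.get(kc, 0)) for kc in kc_ids}
    mean_K = float(np.mean(list(per_cell.values()))) if per_cell else 0.0
    return per_cell, mean_K


def build_weight_matrix(params: KCModelParams, K: int, seed=None) -> np.ndarray:
    """Random M x N weight matrix: per row, a uniform K-subset at 1 - alpha,
    the rest at -alpha.  Every row sums to K - N * alpha exactly."""
    if not (1 <= K <= params.N):
        raise ValueError("K must satisfy 1 <= K <= N")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    M, N, a = params.M, params.N, params.alpha
    W = np.full((M, N), -a)
    # uniform K-subset per row: K smallest of N iid uniforms
    u = rng.random((M, N))
    idx = np.argpartition(u, K - 1, axis=1)[:, :K]
    np.put_along_axis(W, idx, 1.0 - a, axis=1)
    return W


def dimensionality(W: np.ndarray) -> float:
    """Participation ratio (Tr C)^2 / Tr(C^2) of C = W W^T.

    Computed through the N x N Gram matrix G = W^T W, which has the same
    non-zero spectrum as C; range [1, min(M, N)] for non-zero W.
    """
    W = np.asarray(W, dtype=float)
    G = W.T @ W
    tr = np.trace(G)
    tr2 = float(np.sum(G * G))  # Tr(G^2) = ||G||_F^2 (G symmetric)
    if tr2 == 0.0:
        raise ValueError("all-zero weight matrix: dimensionality undefined")
    return float(tr * tr / tr2)


def dimensionality_curve(
    params: KCModelParams, K_range=None
) -> pd.DataFrame:
    """Mean (and sd of) dimensionality over seeded realisations for each K."""
    if K_range is None:
        K_range = range(1, params.N + 1)
    K_range = list(K_range)
    if not K_range:
        raise ValueError("empty K range")
    if max(K_range) > params.N or min(K_range) < 1:
        raise ValueError("K range must lie within [1, N]")
    root = np.random.SeedSequence(params.seed)
    rows = []
    for K, ss in zip(K_range, root.spawn(len(K_range))):
        seeds = ss.generate_state(params.realisations)
        dims = np.array(
            [dimensionality(build_weight_matrix(params, K, seed=int(s)))
             for s in seeds]
        )
        rows.append((K, dims.mean(), dims.std(ddof=1) if len(dims) > 1 else 0.0))
    return pd.DataFrame(rows, columns=["K", "mean_dim", "sd_dim"]).set_index("K")


def optimal_K(curve: pd.DataFrame) -> int:
    """K maximising mean dimensionality; smallest K on ties (plateaus)."""
    best = curve["mean_dim"].max()
    return int(curve.index[curve["mean_dim"] >= best][0])


def budget_fraction(
    edges: EdgeTable,
    source_ids,
    target_partition: dict[str, str],
    direction: str = "output_of_source",
) -> dict[str, float]:
    """Share of a synaptic budget per target group.

    ``output_of_source``: fraction of the source set's output (onto
    partitioned neurons) landing on each group -- e.g. what fraction of the
    APL's output is spent on each KC type.  ``input_of_target``: the source
    set is on the receiving side and fractions apportion its input among
    upstream groups.  Fractions sum to 1 over the partition.
    """
    src = set(source_ids)
    pair = edges.aggregate_neuropils()
    if direction == "output_of_source":
        sel = pair[pair["pre_id"].isin(src) & pair["post_id"].isin(target_partition)]
        groups = sel["post_id"].map(target_partition)
    elif direction == "input_of_target":
        sel = pair[pair["post_id"].isin(src) & pair["pre_id"].isin(target_partition)]
        groups = sel["pre_id"].map(target_partition)
    else:
        raise ValueError("direction must be 'output_of_source' or 'input_of_target'")
    total = sel["weight"].sum()
    if total == 0:
        raise ValueError("zero total budget for the given source/partition")
    frac = sel.groupby(groups)["weight"].sum() / total
    return {g: float(frac.get(g, 0.0)) for g in sorted(set(target_partition.values()))}


def ei_ratio(
    edges: EdgeTable,
    exc_ids,
    inh_ids,
    target_ids,
) -> tuple[dict[str, float], int]:
    """Normalised excitation/inhibition input ratio per target cell.

    Per target: (excitatory input)/(inhibitory input), then divided by the
    cohort mean so the population average is 1 (scale-invariant: doubling
    both E and I inputs leaves the ratio unchanged).  Targets with zero
    inhibitory input have an undefined ratio and are excluded; the count of
    exclusions is returned.
    """
    exc, inh = set(exc_ids), set(inh_ids)
    if exc & inh:
        raise ValueError("excitatory and inhibitory source sets must be disjoint")
    pair = edges.aggregate_neuropils()
    pair = pair[pair["post_id"].isin(set(target_ids))]
    e_in = pair[pair["pre_id"].isin(exc)].groupby("post_id")["weight"].sum()
    i_in = pair[pair["pre_id"].isin(inh)].groupby("post_id")["weight"].sum()
    raw = {}
    excluded = 0
    for t in target_ids:
        e = float(e_in.get(t, 0.0))
        i = float(i_in.get(t, 0.0))
        if i == 0:
            excluded += 1
            continue
        raw[t] = e / i
    if not raw:
        return {}, excluded
    mean = np.mean(list(raw.values()))
    return {t: v / mean for t, v in raw.items()}, excluded
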