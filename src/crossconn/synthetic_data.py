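"""Synthetic multi-hemisphere connectomes with known ground truth.

A :class:`GroundTruthModel` plays the role of a fictive "100%" connectome:
a set of cell types, each with a prototype morphology and a per-hemisphere
target count, and a set of type-level edges with mean weight ``mu`` and a
conservation propensity (the probability the edge is realised at all in any
one hemisphere).  Hemispheres are instantiated from it with biological
variability (cell-count jitter, lognormal edge-weight variation, positional
jitter, mirrored right-side morphologies) and then optionally corrupted with
technical noise (per-neuropil postsynaptic completion rates and synapse
detection precision/recall), so that every downstream stage of the pipeline
can be exercised against a planted answer.

What this emulates -- and what it does not: weights are heavy-tailed
(lognormal mean weights, median 4 synapses), weak edges are less conserved
than strong ones (default propensity mu / (mu + 5)), right-side morphologies
are planar mirror images of the left, and detection errors follow the
published precision/recall of automated synapse detection.  It does not
model segmentation merge/split errors or imaging artefacts as processes;
their net effect is subsumed in completion/precision/recall.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import EdgeTable, NeuronRecord, Skeleton
from .morphology import mirror

__all__ = [
    "GroundTruthType",
    "GroundTruthEdge",
    "GroundTruthModel",
    "BioVariability",
    "TechnicalParams",
    "generate_ground_truth",
    "instantiate_hemisphere",
    "corrupt_hemisphere",
    "simulate_cohort",
]

#: Base neuropil names; hemisphere instantiation appends _L / _R.
DEFAULT_NEUROPILS = ("CA", "LH", "AL", "PLP", "SLP", "AVLP", "SMP", "FB")


@dataclass
class GroundTruthType:
    type_id: str
    target_count: int
    prototype: Skeleton
    soma_xyz: tuple[float, float, float]


@dataclass
class GroundTruthEdge:
    pre_type: str
    post_type: str
    neuropil: str  # base name, no side suffix
    mu: float  # mean weight in synapses, > 0
    conservation: float  # probability the edge is present in a hemisphere


@dataclass
class GroundTruthModel:
    types: list[GroundTruthType]
    edges: list[GroundTruthEdge]
    neuropils: tuple[str, ...] = DEFAULT_NEUROPILS

    def type_ids(self) -> list[str]:
        return [t.type_id for t in self.types]

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.pre_type, e.post_type, e.neuropil, e.mu, e.conservation) for e in self.edges],
            columns=["pre_type", "post_type", "neuropil", "mu", "conservation"],
        )


@dataclass
class BioVariability:
    """Biological variability knobs for hemisphere instantiation.

    ``count_jitter_p`` is the probability a type's cell count deviates by
    +/-1 from target (floored at 1); ``weight_cv`` the coefficient of
    variation of the lognormal per-hemisphere multiplier on edge weight;
    ``morph_jitter_sd_um`` Gaussian positional noise per node; dropout uses
    each planted edge's conservation propensity when ``apply_dropout``.
    """

    count_jitter_p: float = 0.2
    weight_cv: float = 0.3
    morph_jitter_sd_um: float = 0.5
    apply_dropout: bool = True

    def __post_init__(self):
        if min(self.count_jitter_p, self.weight_cv, self.morph_jitter_sd_um) < 0:
            raise ValueError("variability parameters must be >= 0")

    @classmethod
    def none(cls) -> "BioVariability":
        return cls(count_jitter_p=0.0, weight_cv=0.0, morph_jitter_sd_um=0.0,
                   apply_dropout=False)


@dataclass
class TechnicalParams:
    """Per-neuropil completion rates plus detection precision/recall.

    ``completion_rate`` maps sided neuropil names (e.g. ``CA_L``) to
    fractions in (0, 1]; a plain float applies to every neuropil.
    Defaults follow the published synapse-detection operating point
    (precision 0.72, recall 0.77).
    """

    completion_rate: dict | float = 1.0
    precision: float = 0.72
    recall: float = 0.77

    def __post_init__(self):
        rates = (
            [self.completion_rate]
            if np.isscalar(self.completion_rate)
            else list(self.completion_rate.values())
        )
        for r in rates + [self.precision, self.recall]:
            if not (0.0 < r <= 1.0):
                raise ValueError("rates must be in (0, 1]")

    def rate_for(self, neuropil: str) -> float:
        if np.isscalar(self.completion_rate):
            return float(self.completion_rate)
        if neuropil not in self.completion_rate:
            raise ValueError(f"no completion rate for neuropil {neuropil!r}")
        return float(self.completion_rate[neuropil])

    @classmethod
    def perfect(cls) -> "TechnicalParams":
        return cls(completion_rate=1.0, precision=1.0, recall=1.0)


def dropout_probability(mu: float, scale: float = 5.0) -> float:
    """Probability a planted edge of mean weight mu is absent in a hemisphere.

    1 - mu / (mu + scale): non-increasing in mu, so weak edges are the least
    conserved, mirroring the empirical persistence of weak connections.
    """
    if scale <= 0:
        return 0.0
    return float(scale / (mu + scale))


def _random_tree(
    rng: np.random.Generator,
    soma: np.ndarray,
    n_nodes: int,
    step_um: float = 2.0,
    branch_p: float = 0.15,
) -> Skeleton:
    """Random branched tree grown from the soma by persistent random steps."""
    xyz = np.empty((n_nodes, 3))
    parents = np.empty(n_nodes, dtype=np.int64)
    dirs = np.empty((n_nodes, 3))
    xyz[0] = soma
    parents[0] = -1
    dirs[0] = rng.standard_normal(3)
    dirs[0] /= np.linalg.norm(dirs[0])
    tips = [0]
    for i in range(1, n_nodes):
        if len(tips) > 1 and rng.random() < branch_p:
            src = int(rng.integers(0, i))  # start a new branch anywhere
        else:
            src = tips[int(rng.integers(0, len(tips)))]
        step = 0.7 * dirs[src] + 0.7 * rng.standard_normal(3)
        step /= np.linalg.norm(step)
        xyz[i] = xyz[src] + step * step_um
        parents[i] = src
        dirs[i] = step
        if src in tips:
            tips.remove(src)
        tips.append(i)
    return Skeleton(np.arange(1, n_nodes + 1), np.where(parents == -1, -1, parents + 1), xyz)


def generate_ground_truth(
    n_types: int,
    seed: int,
    *,
    median_weight: float = 4.0,
    sigma_log10: float = 0.6,
    mean_count: float = 1.43,
    neuropils: tuple[str, ...] = DEFAULT_NEUROPILS,
    edge_prob: float = 0.35,
    dropout_scale: float = 5.0,
    prototype_nodes: tuple[int, int] = (40, 200),
    min_soma_separation_um: float = 15.0,
    arena_um: float = 120.0,
) -> GroundTruthModel:
    """Draw a ground-truth model: types, prototypes and type-level edges.

    Edge mean weights are lognormal (default median 4 synapses, sigma of
    log10 weight 0.6) so the weight histogram is heavy-tailed like real
    connectomes.  Each ordered type pair sprouts an edge in each neuropil
    independently with ``edge_prob``.  Type somata are kept at least
    ``min_soma_separation_um`` apart so types are morphologically distinct.
    Per-hemisphere target counts are 1 + Poisson(mean_count - 1); the
    default makes ~65% of types singletons, the share observed among
    cross-matched central-brain types.  Deterministic given ``seed``.
    """
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    rng = np.random.default_rng(seed)
    somata: list[np.ndarray] = []
    while len(somata) < n_types:
        cand = rng.uniform([20.0, 0.0, 0.0], [20.0 + arena_um, arena_um, arena_um])
        if all(np.linalg.norm(cand - s) >= min_soma_separation_um for s in somata):
            somata.append(cand)
    types = []
    for i, soma in enumerate(somata):
        n_nodes = int(rng.integers(prototype_nodes[0], prototype_nodes[1] + 1))
        proto = _random_tree(rng, soma, n_nodes)
        count = max(1, int(rng.poisson(mean_count - 1)) + 1)
        types.append(
            GroundTruthType(
                type_id=f"T{i:03d}",
                target_count=count,
                prototype=proto,
                soma_xyz=tuple(soma),
            )
        )
    edges = []
    ids = [t.type_id for t in types]
    for pre in ids:
        for post in ids:
            if pre == post:
                continue
            for np_name in neuropils:
                if rng.random() < edge_prob:
                    mu = float(10 ** rng.normal(math.log10(median_weight), sigma_log10))
                    edges.append(
                        GroundTruthEdge(
                            pre, post, np_name, mu,
                            conservation=1.0 - dropout_probability(mu, dropout_scale),
                        )
                    )
    return GroundTruthModel(types=types, edges=edges, neuropils=tuple(neuropils))


def _sigma_log(cv: float) -> float:
    """Sigma of ln-scale Gaussian giving a lognormal with unit median and CV cv."""
    return math.sqrt(math.log(1.0 + cv * cv))


def instantiate_hemisphere(
    gt: GroundTruthModel,
    dataset: str,
    side: str,
    bio: BioVariability,
    seed: int,
    *,
    midline_x: float = 0.0,
) -> tuple[list[NeuronRecord], dict[str, Skeleton], EdgeTable]:
    """Realise one hemisphere from ground truth.

    Per-type counts are target +/- jitter (min 1); right-side morphologies
    are planar mirrors of the left prototypes plus positional jitter.  Each
    planted edge survives with its conservation propensity; a surviving edge
    realises a type-level weight max(1, round(mu * LogNormal(0, sigma(cv))))
    distributed multinomially over member neuron pairs, so type aggregation
    recovers type-level totals exactly.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    rng = np.random.default_rng(seed)
    suffix = "L" if side == "left" else "R"
    records: list[NeuronRecord] = []
    skeletons: dict[str, Skeleton] = {}
    members: dict[str, list[str]] = {}
    for t in gt.types:
        count = t.target_count
        if bio.count_jitter_p > 0 and rng.random() < bio.count_jitter_p:
            count += int(rng.choice([-1, 1]))
        count = max(1, count)
        members[t.type_id] = []
        for m in range(count):
            nid = f"{dataset}_{suffix}_{t.type_id}_{m:02d}"
            xyz = t.prototype.xyz.copy()
            soma = np.asarray(t.soma_xyz, dtype=float)
            if side == "right":
                xyz = mirror(xyz, midline_x)
                soma = mirror(soma[None, :], midline_x)[0]
            if bio.morph_jitter_sd_um > 0:
                xyz = xyz + rng.normal(0.0, bio.morph_jitter_sd_um, xyz.shape)
            skeletons[nid] = Skeleton(
                t.prototype.node_ids, t.prototype.parent_ids, xyz, t.prototype.radius
            )
            records.append(
                NeuronRecord(
                    neuron_id=nid,
                    dataset=dataset,
                    side=side,
                    soma_xyz=tuple(soma),
                    flow="intrinsic",
                    superclass="central",
                    extra={"gt_type": t.type_id},
                )
            )
            members[t.type_id].append(nid)
    sig = _sigma_log(bio.weight_cv) if bio.weight_cv > 0 else 0.0
    rows = []
    for e in gt.edges:
        if bio.apply_dropout and rng.random() > e.conservation:
            continue
        mult = math.exp(rng.normal(0.0, sig)) if sig > 0 else 1.0
        w = max(1, int(np.round(e.mu * mult)))
        pre_m, post_m = members[e.pre_type], members[e.post_type]
        pairs = [(p, q) for p in pre_m for q in post_m]
        alloc = rng.multinomial(w, np.full(len(pairs), 1.0 / len(pairs)))
        np_name = f"{e.neuropil}_{suffix}"
        for (p, q), k in zip(pairs, alloc):
            if k > 0:
                rows.append((p, q, np_name, int(k)))
    edge_table = EdgeTable(pd.DataFrame(rows, columns=["pre_id", "post_id", "neuropil", "weight"]))
    return records, skeletons, edge_table


def corrupt_hemisphere(
    edges: EdgeTable,
    tech: TechnicalParams,
    seed: int,
    truncation_box: tuple[np.ndarray, np.ndarray] | None = None,
    soma_xyz: dict[str, tuple] | None = None,
    fp_allocation: str = "proportional",
) -> EdgeTable:
    """Apply technical noise to a neuropil-resolved edge table.

    Per synapse, retention is Bernoulli(completion_rate x recall) (a binomial
    thinning per edge).  False positives are then injected so the expected
    FP fraction of the output is 1 - precision; by default they are allocated
    to existing edges proportional to weight (detection errors co-occur with
    real synaptic neuropil and the edge universe stays stable), or uniformly
    over existing edges with ``fp_allocation='uniform'``.  If a truncation box
    is given, neurons whose soma falls outside it are removed first
    (hemibrain-style volume truncation; requires ``soma_xyz``).
    """
    rng = np.random.default_rng(seed)
    df = edges.df.copy()
    if truncation_box is not None:
        if soma_xyz is None:
            raise ValueError("truncation_box requires soma_xyz")
        lo = np.asarray(truncation_box[0], dtype=float)
        hi = np.asarray(truncation_box[1], dtype=float)

        def inside(nid):
            p = np.asarray(soma_xyz[nid], dtype=float)
            return bool(np.all(p >= lo) and np.all(p <= hi))

        keep_ids = {nid for nid in set(df["pre_id"]) | set(df["post_id"]) if inside(nid)}
        df = df[df["pre_id"].isin(keep_ids) & df["post_id"].isin(keep_ids)]
    out_rows = []
    for np_name, grp in df.groupby("neuropil", sort=False):
        rate = tech.rate_for(np_name) * tech.recall
        w = grp["weight"].to_numpy()
        kept = rng.binomial(w, rate)
        total_tp = int(kept.sum())
        n_fp = int(np.round(total_tp * (1.0 - tech.precision) / tech.precision))
        if n_fp > 0:
            if fp_allocation == "proportional":
                p = w / w.sum()
            else:
                p = np.full(len(w), 1.0 / len(w))
            kept = kept + rng.multinomial(n_fp, p)
        for (pre, post), k in zip(grp[["pre_id", "post_id"]].itertuples(index=False), kept):
            if k > 0:
                out_rows.append((pre, post, np_name, int(k)))
    return EdgeTable(
        pd.DataFrame(out_rows, columns=["pre_id", "post_id", "neuropil", "weight"])
    )


def simulate_cohort(
    n_types: int,
    seed: int,
    hemispheres=(("brainA", "left"), ("brainA", "right"), ("brainB", "right")),
    bio: BioVariability | None = None,
    tech: TechnicalParams | None = None,
    **gt_options,
) -> dict:
    """Generate ground truth plus a cohort of (optionally corrupted) hemispheres.

    Returns a dict with the ground-truth model and, per hemisphere tag
    ``"dataset:side"``, records, skeletons and the (corrupted) edge table;
    uncorrupted tables are kept under ``"raw_edges"``.  All randomness is
    derived from ``seed``.
    """
    if bio is None:
        bio = BioVariability()
    gt = generate_ground_truth(n_types, seed, **gt_options)
    out = {"ground_truth": gt, "hemispheres": {}}
    for k, (dataset, side) in enumerate(hemispheres):
        sub = seed + 1000 * (k + 1)
        records, skels, table = instantiate_hemisphere(gt, dataset, side, bio, sub)
        entry = {"records": records, "skeletons": skels, "raw_edges": table}
        if tech is not None:
            entry["edges"] = corrupt_hemisphere(table, tech, sub + 1)
        else:
            entry["edges"] = table
        out["hemispheres"][f"{dataset}:{side}"] = entry
    return out
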