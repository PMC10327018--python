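"""Monte-Carlo model of technical noise in edge weights.

How much of the observed left/right difference in edge weights could be due
to reconstruction alone?  The model builds a fictive "100%" ground truth by
scaling every observed edge weight up by the postsynaptic completion rate of
its neuropil (a 45.8%-complete region scales by 100/45.8 = 2.18), then
repeatedly re-simulates the proofreading and synapse-detection process: a
draw without replacement down to the target completion rate, thinning at the
detection recall, and false-positive injection at the detection precision
(defaults 0.77 and 0.72).  Each round makes two draws -- one with the
original per-neuropil rates and one with the left/right rates flipped -- so
the pair of weights mimics a left/right comparison subject to technical
noise only.  Quantile bands of the flipped draw conditioned on the unflipped
draw's weight (1..30 synapses by default, 500 rounds) then say whether an
observed left/right weight pair is within the range technical noise alone
can explain.

Order of operations is fixed and matters: retain (hypergeometric) -> thin
(recall) -> inject false positives (precision), with FPs allocated to
existing edges proportional to fictive weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import TechnicalParams

__all__ = [
    "NoiseBands",
    "scale_to_fictive",
    "simulate_draw",
    "noise_envelope",
    "fraction_within_band",
    "flip_rates",
]


def _require_columns(df: pd.DataFrame):
    for c in ("pre_type", "post_type", "neuropil", "weight"):
        if c not in df.columns:
            raise ValueError(f"edge frame missing column {c!r}")


def scale_to_fictive(typed_edges: pd.DataFrame, completion_rates: dict) -> pd.DataFrame:
    """Scale observed weights up to a fictive 100%-complete ground truth.

    ``fictive = round(weight / rate)`` with round-half-to-even; fictive
    weights must be integers so synapses can be drawn without replacement.
    ``completion_rates`` maps each neuropil to a fraction in (0, 1].
    """
    _require_columns(typed_edges)
    df = typed_edges.copy()
    rates = df["neuropil"].map(completion_rates)
    if rates.isna().any():
        missing = sorted(df.loc[rates.isna(), "neuropil"].unique())
        raise ValueError(f"no completion rate for neuropils {missing}")
    if (rates <= 0).any():
        raise ValueError("completion rates must be > 0")
    df["fictive"] = np.round(df["weight"] / rates).astype(np.int64)
    return df


def flip_rates(completion_rates: dict) -> dict:
    """Swap the completion rates of mirrored left/right neuropils (X_L <-> X_R)."""
    flipped = {}
    for name, rate in completion_rates.items():
        if name.endswith("_L"):
            other = name[:-2] + "_R"
        elif name.endswith("_R"):
            other = name[:-2] + "_L"
        else:
            raise ValueError(f"neuropil {name!r} has no _L/_R side suffix")
        if other not in completion_rates:
            raise ValueError(f"neuropil {name!r} has no mirrored partner {other!r}")
        flipped[name] = completion_rates[other]
    return flipped


def simulate_draw(
    fictive: pd.DataFrame,
    completion_rates: dict,
    precision: float = 0.72,
    recall: float = 0.77,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One simulated reconstruction: per-edge drawn weights (same row order).

    Per neuropil, exactly round(total x rate) synapses are retained without
    replacement (multivariate hypergeometric across edges), each retained
    synapse is kept with probability ``recall``, and false positives are
    injected so the expected FP fraction of the output is 1 - precision,
    allocated to edges proportional to fictive weight.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if "fictive" not in fictive.columns:
        raise ValueError("run scale_to_fictive first")
    out = np.zeros(len(fictive), dtype=np.int64)
    pos = np.arange(len(fictive))
    for np_name, grp in fictive.groupby("neuropil", sort=False):
        rate = completion_rates.get(np_name)
        if rate is None:
            raise ValueError(f"no completion rate for neuropil {np_name!r}")
        colors = grp["fictive"].to_numpy(dtype=np.int64)
        total = int(colors.sum())
        n_draw = int(np.round(total * rate))
        retained = rng.multivariate_hypergeometric(colors, n_draw)
        if recall < 1.0:
            retained = rng.binomial(retained, recall)
        total_tp = int(retained.sum())
        n_fp = int(np.round(total_tp * (1.0 - precision) / precision))
        if n_fp > 0 and colors.sum() > 0:
            retained = retained + rng.multinomial(n_fp, colors / colors.sum())
        out[pos[fictive["neuropil"] == np_name]] = retained
    return out


@dataclass
class NoiseBands:
    """Quantile envelope of the matched draw conditioned on reference weight."""

    table: pd.DataFrame  # index w; columns mean_diff, abs_mean_diff, q_lo, q_hi, n
    quantiles: tuple[float, float] = (0.05, 0.95)
    rounds: int = 500

    @property
    def w_range(self) -> tuple[int, int]:
        return int(self.table.index.min()), int(self.table.index.max())

    def band(self, w: int) -> tuple[float, float] | None:
        if w not in self.table.index:
            return None
        row = self.table.loc[w]
        return float(row["q_lo"]), float(row["q_hi"])


def noise_envelope(
    fictive: pd.DataFrame,
    completion_rates: dict,
    precision: float = 0.72,
    recall: float = 0.77,
    rounds: int = 500,
    seed: int | None = None,
    w_range: tuple[int, int] = (1, 30),
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> NoiseBands:
    """Noise-only envelope of left/right weight pairs.

    Each round makes an unflipped draw and a draw with left/right completion
    rates swapped; all (w_unflipped, w_flipped) pairs are pooled and, for
    every unflipped weight w in ``w_range``, the mean signed difference
    (unflipped - flipped) and the flipped-weight quantiles are recorded.
    The range defaults to 1..30 synapses, above which edges are too sparse
    to fill the bands.
    """
    flipped_rates = flip_rates(completion_rates)
    rng = np.random.default_rng(seed)
    pairs_u = []
    pairs_f = []
    for _ in range(rounds):
        pairs_u.append(simulate_draw(fictive, completion_rates, precision, recall, rng))
        pairs_f.append(simulate_draw(fictive, flipped_rates, precision, recall, rng))
    wu = np.concatenate(pairs_u)
    wf = np.concatenate(pairs_f)
    rows = []
    for w in range(w_range[0], w_range[1] + 1):
        sel = wf[wu == w]
        if len(sel) == 0:
            continue
        q_lo, q_hi = np.quantile(sel, quantiles)
        rows.append((w, float(np.mean(w - sel)), float(np.mean(np.abs(w - sel))),
                     float(q_lo), float(q_hi), len(sel)))
    table = pd.DataFrame(
        rows, columns=["w", "mean_diff", "abs_mean_diff", "q_lo", "q_hi", "n"]
    ).set_index("w")
    return NoiseBands(table=table, quantiles=quantiles, rounds=rounds)


def fraction_within_band(
    observed_pairs, bands: NoiseBands
) -> tuple[float, pd.DataFrame]:
    """Fraction of observed weight pairs explainable by technical noise alone.

    ``observed_pairs`` is an iterable of (w_left, w_right).  A pair whose
    left weight lies in the band range is in-band iff the right weight falls
    within the closed interval [q_lo(w_left), q_hi(w_left)]; pairs with left
    weight outside the range are excluded and counted separately.
    """
    rows = []
    lo_w, hi_w = bands.w_range
    for wl, wr in observed_pairs:
        wl = int(wl)
        if wl < lo_w or wl > hi_w or wl not in bands.table.index:
            rows.append((wl, wr, "out_of_range"))
            continue
        q_lo, q_hi = bands.band(wl)
        rows.append((wl, wr, "in_band" if q_lo <= wr <= q_hi else "outside"))
    verdicts = pd.DataFrame(rows, columns=["w_left", "w_right", "verdict"])
    considered = verdicts[verdicts["verdict"] != "out_of_range"]
    if len(considered) == 0:
        raise ValueError("no observed pairs within the band range")
    frac = float((considered["verdict"] == "in_band").mean())
    return frac, verdicts
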