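"""Distributional summaries of response-time data.

These statistics serve double duty: they describe empirical or simulated
trial tables (CDF quantiles, conditional accuracy functions, delta plots,
modality-marginal CDFs), and they define the binning from which the fitting
objective is built.

Conventions pinned here:

* Quantiles use linear interpolation between order statistics with plotting
  position (k - 1)/(n - 1) (numpy's default "linear" method).
* CAF bins: trials sorted by RT (stable order for ties) are split into
  near-equal quintiles; when the count is not divisible, the earlier (faster)
  bins receive the extra trials.
* The delta plot's abscissa is the mean of the congruent and incongruent
  quantiles at each probability.
* The RT filter keeps the closed interval [lo, hi] (only strictly faster /
  slower trials are discarded) and always drops censored trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PROBS",
    "DELTA_PROBS",
    "QuantileSet",
    "CAFProfile",
    "filter_rts",
    "cdf_quantiles",
    "caf",
    "caf_bin_counts",
    "delta_function",
    "marginal_cdf",
]

DEFAULT_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)
#: Fine percentile grid used for delta plots (5%, 10%, ..., 95%).
DELTA_PROBS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass(frozen=True)
class QuantileSet:
    """RT quantiles at an ordered set of probabilities."""

    probs: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        values = np.asarray(self.values, dtype=float)
        if len(probs) != len(values):
            raise ValueError("probs and values must have equal length")
        if not all(0 < p < 1 for p in probs):
            raise ValueError("probs must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(probs, probs[1:])):
            raise ValueError("probs must be strictly increasing")
        if np.any(np.diff(values) < 0):
            raise ValueError("quantile values must be non-decreasing")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class CAFProfile:
    """Conditional accuracy function: accuracy per RT quintile bin."""

    bin_edges: np.ndarray  # upper RT edge of each bin except the last (ms)
    accuracy: np.ndarray  # proportion correct per bin
    counts: np.ndarray  # trials per bin

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracy, dtype=float)
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("accuracies must lie in [0, 1]")


def filter_rts(
    table: pd.DataFrame, lo: float = 150.0, hi: float = 1200.0
) -> tuple[pd.DataFrame, float]:
    """Drop censored trials and RTs strictly outside [lo, hi].

    Returns the kept table and the excluded fraction of the input (0 for an
    empty input).  Idempotent by construction.
    """
    if not lo < hi:
        raise ValueError(f"filter bounds must satisfy lo < hi, got {lo} >= {hi}")
    if len(table) == 0:
        return table.copy(), 0.0
    censored = (
        table["censored"].to_numpy(dtype=bool)
        if "censored" in table.columns
        else np.zeros(len(table), dtype=bool)
    )
    rt = table["rt_ms"].to_numpy(dtype=float)
    keep = ~censored & (rt >= lo) & (rt <= hi)
    return table.loc[keep].reset_index(drop=True), float(1.0 - keep.mean())


def cdf_quantiles(rts, probs=DEFAULT_PROBS) -> QuantileSet:
    """RT quantiles by linear interpolation between order statistics."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 5:
        raise ValueError(
            f"need at least 5 observations to estimate quantiles, got {rts.size}"
        )
    values = np.quantile(rts, list(probs), method="linear")
    return QuantileSet(probs=tuple(probs), values=values)


def caf_bin_counts(n: int, n_bins: int) -> np.ndarray:
    """Near-equal bin sizes; earlier bins absorb the remainder."""
    base, rem = divmod(n, n_bins)
    return np.array([base + (1 if i < rem else 0) for i in range(n_bins)])


def caf(table: pd.DataFrame, n_bins: int = 5) -> CAFProfile:
    """Conditional accuracy function over RT quintile bins of one condition.

    All trials — correct and error — are sorted from fastest to slowest
    (stable for ties) and partitioned into ``n_bins`` contiguous bins of
    near-equal count; accuracy is the proportion correct within each bin.
    """
    n = len(table)
    if n == 0:
        raise ValueError("cannot compute a CAF from an empty table")
    if n_bins > n:
        raise ValueError(f"n_bins = {n_bins} exceeds the trial count {n}")
    rt = table["rt_ms"].to_numpy(dtype=float)
    acc = table["accuracy"].to_numpy(dtype=float)
    order = np.argsort(rt, kind="stable")
    rt, acc = rt[order], acc[order]
    counts = caf_bin_counts(n, n_bins)
    stops = np.cumsum(counts)
    starts = stops - counts
    accuracy = np.array([acc[a:b].mean() for a, b in zip(starts, stops)])
    edges = rt[stops[:-1] - 1]  # RT of the slowest trial in each bin but the last
    return CAFProfile(bin_edges=edges, accuracy=accuracy, counts=counts)


def delta_function(cong: QuantileSet, incong: QuantileSet) -> pd.DataFrame:
    """Delta plot: incongruent minus congruent quantile per probability.

    The abscissa pairs each delta with the mean of the two quantiles, so the
    congruency effect is read as a function of overall response speed.
    Negative-going deltas over the slow tail are the signature of a decaying
    automatic pulse.
    """
    if cong.probs != incong.probs:
        raise ValueError("quantile sets must share the same probabilities")
    return pd.DataFrame(
        {
            "prob": cong.probs,
            "midpoint_ms": (cong.values + incong.values) / 2.0,
            "delta_ms": incong.values - cong.values,
        }
    )


def marginal_cdf(tables, probs=DEFAULT_PROBS) -> QuantileSet:
    """Modality-marginal CDF: per-condition quantiles averaged pointwise.

    ``tables`` holds the trial tables of one fixed label of the modality of
    interest across all labels of the other modality (e.g. visual-congruent
    crossed with the three tactile labels).  Quantiles are computed per
    condition and then averaged — not pooled — matching how marginal CDFs
    are reported for this design.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one condition table")
    if any(t is None or len(t) == 0 for t in tables):
        raise ValueError("every condition table must be present and non-empty")
    stacked = np.vstack(
        [cdf_quantiles(t["rt_ms"].to_numpy(dtype=float), probs).values for t in tables]
    )
    return QuantileSet(probs=tuple(probs), values=stacked.mean(axis=0))
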