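"""Recombination statistics over peak sets.

The central quantities: the mean recombination rate at peak centers (the
screening statistic used to rank candidate binding proteins), rate metaplots
around centers, the genetic distance accumulated across a flanking window
(compared against a random-region null), the share of peaks sitting below the
genome-average rate (cold-spot enrichment), and a two-sample Student's t
comparison for observed-vs-null vectors reported as mean +/- SEM.

Peaks whose center falls outside the mapped span are excluded from averages
(imputing the outside rate of 0 would bias every statistic toward "cold");
the exclusion count travels with each result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .genmap import GeneticMap, genome_average_rate
from .intervals import PeakSet

__all__ = [
    "MeanRateResult",
    "RateProfile",
    "TTestComparison",
    "mean_center_rate",
    "rate_profile",
    "flank_genetic_distance",
    "fraction_below_average",
    "compare_to_null",
    "center_rates",
]


@dataclass(frozen=True)
class MeanRateResult:
    mean: float
    sem: float
    n_used: int
    n_excluded: int


@dataclass
class RateProfile:
    """Mean rate (cM/Mb) as a function of offset from the peak center."""

    offsets: np.ndarray        # bp, symmetric about 0
    mean_rate: np.ndarray
    sem: np.ndarray
    n_peaks: np.ndarray        # peaks contributing per offset

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean_rate": self.mean_rate,
                             "sem": self.sem, "n": self.n_peaks})


@dataclass(frozen=True)
class TTestComparison:
    t: float
    p: float
    mean_observed: float
    sem_observed: float
    mean_null: float
    sem_null: float
    n_observed: int
    n_null: int


def center_rates(
    peaks: PeakSet, maps: Mapping[str, GeneticMap]
) -> tuple[np.ndarray, int]:
    """Rate at each usable peak center; returns (rates, n_excluded).

    Excluded peaks: chromosome absent from the map collection, or center
    outside the mapped span.
    """
    rates: list[np.ndarray] = []
    n_excluded = 0
    df = peaks.to_dataframe()
    if df.empty:
        return np.empty(0), 0
    df["center"] = (df["start"] + df["end"]) // 2
    for chrom, sub in df.groupby("chrom", sort=False):
        gmap = maps.get(chrom)
        if gmap is None:
            n_excluded += len(sub)
            continue
        vals, in_map = gmap.rate_at_many(sub["center"].to_numpy())
        rates.append(vals[in_map])
        n_excluded += int((~in_map).sum())
    if rates:
        return np.concatenate(rates), n_excluded
    return np.empty(0), n_excluded


def _mean_sem(vals: np.ndarray) -> tuple[float, float]:
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan
    return mean, sem


def mean_center_rate(
    peaks: PeakSet, maps: Mapping[str, GeneticMap]
) -> MeanRateResult:
    """Mean +/- SEM of the recombination rate at peak centers."""
    vals, n_excluded = center_rates(peaks, maps)
    if vals.size == 0:
        raise ValidationError(
            f"mean_center_rate({peaks.label!r}): no peak center falls inside the map "
            f"({n_excluded} excluded)"
        )
    mean, sem = _mean_sem(vals)
    return MeanRateResult(mean=mean, sem=sem, n_used=vals.size, n_excluded=n_excluded)


def rate_profile(
    peaks: PeakSet,
    maps: Mapping[str, GeneticMap],
    flank: int = 5000,
    step: int = 50,
) -> RateProfile:
    """Mean rate at every offset in {-flank, ..., 0, ..., +flank} (step bp)
    relative to peak centers — the rate metaplot around binding sites."""
    if flank <= 0:
        raise ValueError("rate_profile: flank must be > 0")
    if step <= 0 or flank % step:
        raise ValueError("rate_profile: step must be > 0 and divide flank")
    offsets = np.arange(-flank, flank + 1, step, dtype=np.int64)
    k = offsets.size
    s = np.zeros(k)
    ss = np.zeros(k)
    n = np.zeros(k, dtype=np.int64)
    df = peaks.to_dataframe()
    if df.empty:
        raise ValidationError("rate_profile: empty peak set")
    df["center"] = (df["start"] + df["end"]) // 2
    for chrom, sub in df.groupby("chrom", sort=False):
        gmap = maps.get(chrom)
        if gmap is None:
            continue
        grid = sub["center"].to_numpy()[:, None] + offsets[None, :]
        vals, in_map = gmap.rate_at_many(grid.ravel())
        vals = vals.reshape(grid.shape)
        in_map = in_map.reshape(grid.shape)
        vals = np.where(in_map, vals, 0.0)
        s += vals.sum(axis=0)
        ss += (vals ** 2).sum(axis=0)
        n += in_map.sum(axis=0)
    if n.sum() == 0:
        raise ValidationError(f"rate_profile({peaks.label!r}): no usable peak at any offset")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        var = (ss - n * mean ** 2) / np.maximum(n - 1, 1)
        var = np.clip(var, 0.0, None)  # guard tiny negative round-off
        sem = np.where(n > 1, np.sqrt(var / np.maximum(n, 1)), np.nan)
    return RateProfile(offsets=offsets, mean_rate=mean, sem=sem, n_peaks=n)


def flank_genetic_distance(
    peaks: PeakSet,
    maps: Mapping[str, GeneticMap],
    flank: int = 10000,
    *,
    anchor: str = "center",
) -> pd.DataFrame:
    """Genetic distance (cM) across [anchor - flank, anchor + flank] per peak.

    ``anchor="center"`` spans peak center +/- flank (default); ``"edges"``
    spans [start - flank, end + flank].  Windows reaching beyond the mapped
    span are clamped to the terminal anchors and flagged in the ``clamped``
    column.  Peaks on unmapped chromosomes are dropped.
    """
    if flank < 0:
        raise ValueError("flank_genetic_distance: flank must be >= 0")
    if anchor not in ("center", "edges"):
        raise ValueError(f"flank_genetic_distance: unknown anchor {anchor!r}")
    df = peaks.to_dataframe()
    if df.empty:
        raise ValidationError("flank_genetic_distance: empty peak set")
    df["center"] = (df["start"] + df["end"]) // 2
    parts = []
    for chrom, sub in df.groupby("chrom", sort=False):
        gmap = maps.get(chrom)
        if gmap is None:
            continue
        if anchor == "center":
            left = sub["center"].to_numpy() - flank
            right = sub["center"].to_numpy() + flank
        else:
            left = sub["start"].to_numpy() - flank
            right = sub["end"].to_numpy() + flank
        cm_l, cl_l = gmap.cm_at_many(left)
        cm_r, cl_r = gmap.cm_at_many(right)
        out = sub[["chrom", "start", "end", "center"]].copy()
        out["cm"] = cm_r - cm_l
        out["clamped"] = cl_l | cl_r
        parts.append(out)
    if not parts:
        raise ValidationError(
            f"flank_genetic_distance({peaks.label!r}): no peak on a mapped chromosome"
        )
    return pd.concat(parts, ignore_index=True)


def fraction_below_average(
    peaks: PeakSet, maps: Mapping[str, GeneticMap]
) -> float:
    """Share of usable peaks whose center rate is strictly below the
    physical-length-weighted genome-average rate."""
    vals, _ = center_rates(peaks, maps)
    if vals.size == 0:
        raise ValidationError("fraction_below_average: no usable peaks")
    avg = genome_average_rate(maps)
    return float((vals < avg).mean())


def compare_to_null(observed, null, *, welch: bool = False) -> TTestComparison:
    """Two-sided two-sample t-test (pooled variance by default) plus the
    mean +/- SEM of each group, the form every comparison here is reported in.

    Degenerate case: when both groups are constant and equal the statistic is
    defined as t = 0, p = 1 (no evidence of a difference).
    """
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null, dtype=float)
    if obs.size < 2 or nul.size < 2:
        raise ValidationError("compare_to_null: both vectors need length >= 2")
    mo, so = _mean_sem(obs)
    mn, sn = _mean_sem(nul)
    if obs.std(ddof=1) == 0.0 and nul.std(ddof=1) == 0.0:
        if mo == mn:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, mo - mn), 0.0
    else:
        res = stats.ttest_ind(obs, nul, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
    return TTestComparison(t=t, p=p, mean_observed=mo, sem_observed=so,
                           mean_null=mn, sem_null=sn,
                           n_observed=obs.size, n_null=nul.size)
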