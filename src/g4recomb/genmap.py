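"""Genetic-map engine: physical position (bp) <-> genetic position (cM) queries.

A genetic map is a per-chromosome table of anchors ``(position, rate, cum_cm)``
in the HapMap/1000 Genomes convention: the recombination rate (cM/Mb) attached
to anchor *i* applies on the half-open physical interval ``[pos_i, pos_{i+1})``
and the cumulative genetic position (cM) accumulates linearly within each
interval.  The last anchor carries no forward interval.  Every recombination
statistic in this package reduces to the three queries implemented here:
point rate lookup, cumulative-cM interpolation, and genetic distance between
two physical positions.

Coordinates are 0-based internally; source map files (1-based) are shifted on
load.  Positions outside the mapped span are a *policy*, not an error: rate
queries return a configurable outside value (default 0.0 cM/Mb) and a flag,
cumulative-cM queries clamp to the nearest terminal anchor and flag.  Callers
that compute averages drop flagged positions by default and report the count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .util import normalize_chromosome

__all__ = [
    "GeneticMap",
    "load_genetic_map",
    "write_genetic_map",
    "rate_at",
    "cm_at",
    "genetic_distance",
    "genome_average_rate",
]

#: tolerance (cM) for the cum-cM self-consistency check at load time
CONSISTENCY_TOL_CM = 1e-6


@dataclass
class GeneticMap:
    """Piecewise-constant recombination map for one chromosome.

    Parameters
    ----------
    chromosome
        Normalized chromosome label.
    positions
        Strictly increasing anchor positions (bp, 0-based).
    rates
        Recombination rate (cM/Mb) on ``[positions[i], positions[i+1])``;
        finite and >= 0.
    cum_cm
        Cumulative genetic position (cM) at each anchor; non-decreasing.
    """

    chromosome: str
    positions: np.ndarray
    rates: np.ndarray
    cum_cm: np.ndarray
    outside_rate: float = 0.0
    _consistent: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        self.cum_cm = np.asarray(self.cum_cm, dtype=float)
        if self.positions.size == 0:
            raise ValidationError(f"{self.chromosome}: genetic map has no anchors")
        if not (self.positions.size == self.rates.size == self.cum_cm.size):
            raise ValidationError(f"{self.chromosome}: anchor arrays differ in length")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValidationError(
                f"{self.chromosome}: anchor positions must be strictly increasing"
            )
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates < 0):
            raise ValidationError(f"{self.chromosome}: rates must be finite and >= 0")
        if self.positions.size > 1 and np.any(np.diff(self.cum_cm) < -CONSISTENCY_TOL_CM):
            raise ValidationError(f"{self.chromosome}: cumulative cM must be non-decreasing")
        self._check_consistency()

    def _check_consistency(self) -> None:
        """Warn (not fail) when cum_cm disagrees with the integral of the rates."""
        if self.positions.size < 2:
            return
        expected = self.cum_cm[:-1] + self.rates[:-1] * np.diff(self.positions) / 1e6
        err = np.abs(expected - self.cum_cm[1:])
        if err.max() > CONSISTENCY_TOL_CM:
            self._consistent = False
            warnings.warn(
                f"{self.chromosome}: cumulative cM inconsistent with rates "
                f"(max deviation {err.max():.3g} cM > {CONSISTENCY_TOL_CM:g})",
                stacklevel=3,
            )

    # -- span ---------------------------------------------------------------
    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1])

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def span_cm(self) -> float:
        return float(self.cum_cm[-1] - self.cum_cm[0])

    # -- queries ------------------------------------------------------------
    def rate_at_many(self, positions) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized point-rate lookup.

        Returns ``(rates, in_map)``; out-of-map entries carry ``outside_rate``
        and ``in_map == False``.  Positions at or beyond the last anchor are
        outside (the last anchor has no forward interval).
        """
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        idx = np.searchsorted(self.positions, pos, side="right") - 1
        in_map = (idx >= 0) & (pos < self.positions[-1])
        vals = np.where(in_map, self.rates[np.clip(idx, 0, self.rates.size - 1)],
                        self.outside_rate)
        return vals.astype(float), in_map

    def rate_at(self, position: int) -> float:
        return float(self.rate_at_many([position])[0][0])

    def cm_at_many(self, positions) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized cumulative-cM interpolation.

        Returns ``(cm, clamped)``; positions outside the mapped span are
        clamped to the terminal anchors' cum_cm and flagged.
        """
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        clamped = (pos < self.positions[0]) | (pos > self.positions[-1])
        pc = np.clip(pos, self.positions[0], self.positions[-1])
        idx = np.clip(np.searchsorted(self.positions, pc, side="right") - 1,
                      0, self.positions.size - 1)
        cm = self.cum_cm[idx] + self.rates[idx] * (pc - self.positions[idx]) / 1e6
        return cm.astype(float), clamped

    def cm_at(self, position: int) -> float:
        return float(self.cm_at_many([position])[0][0])

    def genetic_distance(self, start: int, end: int) -> float:
        """Genetic distance (cM) accumulated between two physical positions."""
        if start > end:
            raise ValueError(f"genetic_distance: start {start} > end {end}")
        return self.cm_at(end) - self.cm_at(start)


# ---------------------------------------------------------------------------
# module-level operation wrappers (the names the rest of the package uses)
# ---------------------------------------------------------------------------

def rate_at(gmap: GeneticMap, position: int) -> float:
    return gmap.rate_at(position)


def cm_at(gmap: GeneticMap, position: int) -> float:
    return gmap.cm_at(position)


def genetic_distance(gmap: GeneticMap, start: int, end: int) -> float:
    return gmap.genetic_distance(start, end)


def genome_average_rate(maps: Mapping[str, GeneticMap] | Iterable[GeneticMap]) -> float:
    """Physical-length-weighted mean recombination rate over all mapped spans.

    Equals total genetic length / total physical length, i.e. the per-bp mean
    of ``rate_at`` over the union of mapped intervals.  Single-anchor maps have
    zero span and are skipped; if every map is degenerate this is undefined.
    """
    if isinstance(maps, Mapping):
        maps = maps.values()
    total_cm = 0.0
    total_bp = 0
    for m in maps:
        if m.positions.size < 2:
            continue
        total_cm += m.span_cm
        total_bp += m.span_bp
    if total_bp == 0:
        raise ValidationError("genome_average_rate: no map with >= 2 anchors")
    return total_cm / total_bp * 1e6


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_genetic_map(
    path,
    chromosome_filter: set[str] | None = None,
    *,
    one_based: bool = True,
    strip_prefix: str = "chr",
    sep: str = r"\s+",
    outside_rate: float = 0.0,
) -> dict[str, GeneticMap]:
    """Read a genetic-map table into one :class:`GeneticMap` per chromosome.

    Expected layout: a header line then whitespace/tab-delimited rows
    ``chromosome  position(bp)  rate(cM/Mb)  map(cM)`` (columns by order, so
    header wording does not matter). Gzip is handled transparently. Source
    positions are 1-based by default and shifted to the package-wide 0-based
    convention on load.
    """
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str, comment=None)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty genetic-map file") from exc
    if df.shape[0] == 0:
        raise ParseError(f"{path}: genetic-map file has a header but no rows")
    if df.shape[1] < 4:
        raise ParseError(f"{path}: expected 4 columns (chrom pos rate cM), got {df.shape[1]}")

    chrom = df.iloc[:, 0].map(lambda c: normalize_chromosome(c, strip_prefix))
    pos = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    rate = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    cm = pd.to_numeric(df.iloc[:, 3], errors="coerce")
    bad = pos.isna() | rate.isna() | cm.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise ParseError(f"{path}: malformed row at line {line}")

    maps: dict[str, GeneticMap] = {}
    frame = pd.DataFrame({
        "chrom": chrom,
        "pos": pos.astype(np.int64) - (1 if one_based else 0),
        "rate": rate.astype(float),
        "cm": cm.astype(float),
    })
    for name, sub in frame.groupby("chrom", sort=True):
        if chromosome_filter is not None and name not in chromosome_filter:
            continue
        sub = sub.sort_values("pos", kind="mergesort")
        if sub["pos"].duplicated().any():
            raise ValidationError(f"{path}: duplicate positions on chromosome {name}")
        maps[str(name)] = GeneticMap(
            chromosome=str(name),
            positions=sub["pos"].to_numpy(),
            rates=sub["rate"].to_numpy(),
            cum_cm=sub["cm"].to_numpy(),
            outside_rate=outside_rate,
        )
    if not maps:
        raise ValidationError(f"{path}: no chromosomes left after filtering")
    return maps


def write_genetic_map(maps: Mapping[str, GeneticMap], path, *, one_based: bool = True) -> None:
    """Write maps back to the 4-column text format (round-trips with the loader)."""
    rows = []
    for name in sorted(maps):
        m = maps[name]
        for p, r, c in zip(m.positions, m.rates, m.cum_cm):
            rows.append((name, int(p) + (1 if one_based else 0), float(r), float(c)))
    df = pd.DataFrame(rows, columns=["chromosome", "position", "rate_cM_Mb", "map_cM"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
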