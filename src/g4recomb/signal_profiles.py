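"""Binned signal aggregation around peak centers (computeMatrix-style metaplots).

A signal track is a step function (bedGraph).  For every peak the window
[center - flank, center + flank) is cut into fixed-width bins and each bin
takes the coverage-weighted mean of the track over the bin, with uncovered
bases contributing value 0 by default (deepTools' missing-data-as-zero
behaviour; a skip-missing mode is available).  The aggregate profile is the
per-bin mean over peaks (mean of per-peak bin means), reported with SEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .intervals import PeakSet
from .util import normalize_chromosome

__all__ = ["SignalTrack", "ProfileMatrix", "read_bedgraph", "write_bedgraph",
           "compute_matrix"]


@dataclass
class SignalTrack:
    """Sorted, non-overlapping value steps for one chromosome."""

    chromosome: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    _bp: np.ndarray = field(default=None, repr=False)      # breakpoints
    _segval: np.ndarray = field(default=None, repr=False)  # value per segment
    _cum: np.ndarray = field(default=None, repr=False)     # integral at breakpoints
    _cumcov: np.ndarray = field(default=None, repr=False)  # covered-bp at breakpoints

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.starts.size == self.ends.size == self.values.size):
            raise ValidationError(f"{self.chromosome}: step arrays differ in length")
        if np.any(self.starts >= self.ends):
            raise ValidationError(f"{self.chromosome}: inverted step interval")
        if self.starts.size > 1:
            order = np.argsort(self.starts, kind="mergesort")
            self.starts, self.ends, self.values = (
                self.starts[order], self.ends[order], self.values[order])
            if np.any(self.starts[1:] < self.ends[:-1]):
                raise ValidationError(f"{self.chromosome}: overlapping steps")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.chromosome}: non-finite signal value")
        self._build_integral()

    def _build_integral(self) -> None:
        """Precompute piecewise-linear antiderivatives of value and coverage."""
        n = self.starts.size
        if n == 0:
            self._bp = np.array([0], dtype=np.int64)
            self._segval = np.array([0.0])
            self._cum = np.array([0.0])
            self._cumcov = np.array([0.0])
            return
        bp = np.empty(2 * n, dtype=np.int64)
        bp[0::2], bp[1::2] = self.starts, self.ends
        segval = np.zeros(2 * n - 1)
        segcov = np.zeros(2 * n - 1)
        segval[0::2] = self.values          # covered segments; gaps stay 0
        segcov[0::2] = 1.0
        widths = np.diff(bp).astype(float)
        self._bp = bp
        self._segval = np.append(segval, 0.0)   # sentinel for idx == 2n-1
        self._cum = np.concatenate([[0.0], np.cumsum(segval * widths)])
        self._cumcov = np.concatenate([[0.0], np.cumsum(segcov * widths)])

    def _antideriv(self, x: np.ndarray, cum: np.ndarray, cov: bool) -> np.ndarray:
        xc = np.clip(x, self._bp[0], self._bp[-1])
        idx = np.clip(np.searchsorted(self._bp, xc, side="right") - 1,
                      0, self._bp.size - 1)
        if cov:
            # even segment index = covered step, odd = gap; last breakpoint has
            # zero forward width so its slope never matters but is zeroed anyway
            slope = np.where((idx % 2 == 0) & (idx < self._bp.size - 1), 1.0, 0.0)
        else:
            slope = self._segval[idx]
        return cum[idx] + slope * (xc - self._bp[idx])

    def integral(self, a, b) -> np.ndarray:
        """Integral of the track value over [a, b) (vectorized)."""
        a = np.atleast_1d(np.asarray(a, dtype=np.int64))
        b = np.atleast_1d(np.asarray(b, dtype=np.int64))
        return (self._antideriv(b, self._cum, cov=False)
                - self._antideriv(a, self._cum, cov=False))

    def coverage(self, a, b) -> np.ndarray:
        """Covered bp within [a, b) (vectorized)."""
        a = np.atleast_1d(np.asarray(a, dtype=np.int64))
        b = np.atleast_1d(np.asarray(b, dtype=np.int64))
        return (self._antideriv(b, self._cumcov, cov=True)
                - self._antideriv(a, self._cumcov, cov=True))

    def value_at(self, position: int) -> float:
        """Point lookup (0 in gaps / outside)."""
        return float(self.integral(position, position + 1)[0])


@dataclass
class ProfileMatrix:
    """Per-peak binned signal around centers plus the aggregate profile."""

    offsets: np.ndarray          # bin-center offsets from the peak center (bp)
    matrix: np.ndarray           # (n_peaks, n_bins)
    aggregate: np.ndarray        # per-bin mean over peaks
    sem: np.ndarray
    n_dropped: int = 0

    @property
    def n_peaks(self) -> int:
        return self.matrix.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.aggregate,
                             "sem": self.sem})


def read_bedgraph(path, *, strip_prefix: str = "chr") -> dict[str, SignalTrack]:
    """Read a 4-column bedGraph into per-chromosome :class:`SignalTrack` s.

    Overlapping or inverted input intervals raise a validation error naming
    the line; an empty file yields an empty collection.
    """
    rows: dict[str, list[tuple[int, int, float, int]]] = {}
    import gzip
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = normalize_chromosome(fields[0], strip_prefix)
            try:
                s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph row") from exc
            if s >= e:
                raise ValidationError(f"{path}:{lineno}: inverted interval {s}>={e}")
            rows.setdefault(chrom, []).append((s, e, v, lineno))
    tracks: dict[str, SignalTrack] = {}
    for chrom, recs in rows.items():
        recs.sort()
        for (s1, e1, _, _), (s2, _, _, ln2) in zip(recs, recs[1:]):
            if s2 < e1:
                raise ValidationError(f"{path}:{ln2}: interval overlaps the previous "
                                      f"one on chromosome {chrom}")
        arr = np.array([(s, e, v) for s, e, v, _ in recs])
        tracks[chrom] = SignalTrack(chrom, arr[:, 0], arr[:, 1], arr[:, 2])
    return tracks


def write_bedgraph(tracks: Mapping[str, SignalTrack], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for s, e, v in zip(t.starts, t.ends, t.values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def compute_matrix(
    peaks: PeakSet,
    tracks: Mapping[str, SignalTrack],
    flank: int = 5000,
    bin: int = 50,
    *,
    missing_as_zero: bool = True,
) -> ProfileMatrix:
    """Bin the track signal over [center - flank, center + flank) per peak.

    Bin value = coverage-weighted mean of the track over the bin; with the
    default ``missing_as_zero`` uncovered bases count as value 0 (divide by
    bin width), otherwise the bin averages covered bases only (NaN if none,
    ignored in the aggregate).  Peaks on chromosomes with no track are dropped
    and counted in ``n_dropped``.
    """
    if flank <= 0 or bin <= 0 or (2 * flank) % bin:
        raise ValueError("compute_matrix: need flank, bin > 0 with bin | 2*flank")
    n_bins = 2 * flank // bin
    edges_rel = -flank + bin * np.arange(n_bins + 1, dtype=np.int64)
    offsets = edges_rel[:-1] + bin // 2
    rows: list[np.ndarray] = []
    n_dropped = 0
    for p in peaks:
        track = tracks.get(p.chromosome)
        if track is None:
            n_dropped += 1
            continue
        edges = p.center + edges_rel
        sums = track.integral(edges[:-1], edges[1:])
        if missing_as_zero:
            rows.append(sums / bin)
        else:
            cov = track.coverage(edges[:-1], edges[1:])
            with np.errstate(invalid="ignore", divide="ignore"):
                rows.append(np.where(cov > 0, sums / np.maximum(cov, 1e-300), np.nan))
    if not rows:
        raise ValidationError(f"compute_matrix({peaks.label!r}): no usable peaks")
    matrix = np.vstack(rows)
    with np.errstate(invalid="ignore"):
        aggregate = np.nanmean(matrix, axis=0)
        n_eff = np.sum(~np.isnan(matrix), axis=0)
        sd = np.nanstd(matrix, axis=0, ddof=1)
        sem = np.where(n_eff > 1, sd / np.sqrt(np.maximum(n_eff, 1)), np.nan)
    return ProfileMatrix(offsets=offsets, matrix=matrix, aggregate=aggregate,
                         sem=sem, n_dropped=n_dropped)
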