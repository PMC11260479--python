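"""Peak intervals: BED/narrowPeak I/O, centers, overlap, and random-region nulls.

All intervals are 0-based half-open ``[start, end)`` (native BED convention).
Touching intervals (``a.end == b.start``) therefore do *not* overlap, matching
the bedtools default used throughout the field.
"""

from __future__ import annotations

import gzip
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ParseError, ValidationError
from .genmap import GeneticMap
from .util import normalize_chromosome

__all__ = [
    "Peak",
    "PeakSet",
    "read_peaks",
    "write_peaks",
    "peak_center",
    "overlap_wa",
    "random_peaks",
    "stratify_by_enrichment",
    "bounds_from_maps",
]


@dataclass(frozen=True)
class Peak:
    """One genomic interval, optionally carrying a peak-calling enrichment value."""

    chromosome: str
    start: int
    end: int
    name: str | None = None
    enrichment: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"peak {self.chromosome}:{self.start}-{self.end}: start must be < end"
            )
        if self.enrichment is not None and self.enrichment < 0:
            raise ValidationError(
                f"peak {self.chromosome}:{self.start}-{self.end}: negative enrichment"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def peak_center(peak: Peak) -> int:
    """Center position, floor((start + end) / 2) — the anchor for every
    rate/profile statistic in the package."""
    return peak.center


@dataclass
class PeakSet:
    """An ordered, labelled collection of peaks (one ChIP-seq/CUT&Tag dataset)."""

    label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = Counter((p.chromosome, p.start, p.end) for p in self.peaks)
        dups = sum(c - 1 for c in seen.values())
        if dups:
            warnings.warn(f"PeakSet {self.label!r}: {dups} duplicate interval(s)",
                          stacklevel=3)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def chromosomes(self) -> list[str]:
        return sorted({p.chromosome for p in self.peaks})

    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.peaks], dtype=np.int64)

    def lengths(self) -> np.ndarray:
        return np.array([p.length for p in self.peaks], dtype=np.int64)

    def enrichments(self) -> np.ndarray:
        vals = [p.enrichment for p in self.peaks]
        if any(v is None for v in vals):
            raise ValidationError(f"PeakSet {self.label!r}: missing enrichment values")
        return np.array(vals, dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chromosome for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "name": [p.name if p.name is not None else "." for p in self.peaks],
                "enrichment": [p.enrichment for p in self.peaks],
            }
        )

    def interval_trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for i, p in enumerate(self.peaks):
            trees.setdefault(p.chromosome, IntervalTree()).addi(p.start, p.end, i)
        return trees


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMAT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_peaks(
    path,
    format: str = "auto",
    *,
    label: str | None = None,
    strip_prefix: str = "chr",
) -> PeakSet:
    """Read BED3/BED6/ENCODE narrowPeak into a :class:`PeakSet`.

    ``format="auto"`` infers from the extension (``.narrowPeak``) or the column
    count of the first data line. narrowPeak column 7 (signalValue) becomes the
    peak's enrichment; BED files carry no enrichment.
    """
    if format not in ("auto", *_FORMAT_COLUMNS):
        raise ValueError(f"unknown peak format {format!r}")
    peaks: list[Peak] = []
    fmt = format
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "auto":
                if str(path).endswith(".narrowPeak") or len(fields) == 10:
                    fmt = "narrowPeak"
                elif len(fields) >= 6:
                    fmt = "bed6"
                else:
                    fmt = "bed3"
            need = _FORMAT_COLUMNS[fmt]
            if len(fields) < need:
                raise ParseError(f"{path}:{lineno}: expected >= {need} columns for "
                                 f"{fmt}, got {len(fields)}")
            chrom = normalize_chromosome(fields[0], strip_prefix)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if need > 3 and fields[3] != "." else None
            enrichment = None
            if fmt == "narrowPeak":
                try:
                    enrichment = float(fields[6])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad signalValue") from exc
            peaks.append(Peak(chrom, start, end, name=name, enrichment=enrichment))
    return PeakSet(label=label or str(path), peaks=peaks)


def write_peaks(peaks: PeakSet, path, format: str = "bed6") -> None:
    """Write BED6 (enrichment in column 5, a documented non-standard use) or
    10-column narrowPeak (enrichment as signalValue, summit -1)."""
    if format not in ("bed3", "bed6", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name if p.name is not None else f"peak_{i}"
            e = 0.0 if p.enrichment is None else p.enrichment
            if format == "bed3":
                fh.write(f"{p.chromosome}\t{p.start}\t{p.end}\n")
            elif format == "bed6":
                fh.write(f"{p.chromosome}\t{p.start}\t{p.end}\t{name}\t{e:g}\t.\n")
            else:
                fh.write(f"{p.chromosome}\t{p.start}\t{p.end}\t{name}\t0\t.\t"
                         f"{e:g}\t-1\t-1\t-1\n")


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def overlap_wa(a: PeakSet, b: PeakSet, dedupe: bool = True) -> PeakSet:
    """Peaks of ``a`` overlapping >= 1 bp of any peak in ``b``.

    Mirrors ``bedtools intersect -a A -b B -wa``: with ``dedupe=False`` one
    output record per overlapping (a, b) pair; with ``dedupe=True`` (the
    default used by every downstream statistic) each qualifying ``a`` peak
    appears once, in input order.
    """
    trees = b.interval_trees()
    out: list[Peak] = []
    for p in a.peaks:
        tree = trees.get(p.chromosome)
        if tree is None:
            continue
        hits = tree.overlap(p.start, p.end)
        if not hits:
            continue
        out.extend([p] if dedupe else [p] * len(hits))
    return PeakSet(label=f"{a.label}&{b.label}", peaks=out)


def complement_wa(a: PeakSet, b: PeakSet) -> PeakSet:
    """Peaks of ``a`` overlapping nothing in ``b`` (the -v counterpart)."""
    trees = b.interval_trees()
    out = [p for p in a.peaks
           if not (t := trees.get(p.chromosome)) or not t.overlap(p.start, p.end)]
    return PeakSet(label=f"{a.label}-{b.label}", peaks=out)


# ---------------------------------------------------------------------------
# random-region null
# ---------------------------------------------------------------------------

def bounds_from_maps(maps: Mapping[str, GeneticMap]) -> dict[str, tuple[int, int]]:
    """Per-chromosome (min, max) placement bounds = the mapped span."""
    return {name: (m.start, m.end) for name, m in maps.items()}


def random_peaks(
    template: PeakSet,
    bounds: Mapping[str, tuple[int, int]],
    n: int,
    *,
    match_lengths: bool = True,
    fixed_length: int = 200,
    seed: int = 0,
) -> PeakSet:
    """Seeded random-region null matched to a template peak set.

    Chromosome assignment follows the template's per-chromosome proportions;
    lengths are resampled with replacement from the template (or fixed at
    ``fixed_length``); positions are independent uniform draws within the
    per-chromosome bounds.  No overlap-avoidance is applied: draws are
    independent, and collisions among null peaks are simply allowed.
    Bit-reproducible for a given seed.
    """
    if len(template) == 0:
        raise ValidationError("random_peaks: empty template")
    chroms = template.chromosomes()
    missing = [c for c in chroms if c not in bounds]
    if missing:
        raise ValidationError(f"random_peaks: no bounds for chromosome(s) {missing}")
    counts = Counter(p.chromosome for p in template)
    props = np.array([counts[c] for c in chroms], dtype=float)
    props /= props.sum()
    lengths_pool = template.lengths() if match_lengths else np.array([fixed_length])
    max_len = int(lengths_pool.max())
    for c in chroms:
        lo, hi = bounds[c]
        if hi - lo < max_len:
            raise ValidationError(
                f"random_peaks: chromosome {c} span {hi - lo} bp cannot place the "
                f"longest template peak ({max_len} bp)"
            )

    rng = np.random.default_rng(seed)
    chrom_idx = rng.choice(len(chroms), size=n, p=props)
    lengths = rng.choice(lengths_pool, size=n, replace=True)
    starts = np.empty(n, dtype=np.int64)
    for ci, c in enumerate(chroms):
        mask = chrom_idx == ci
        if not mask.any():
            continue
        lo, hi = bounds[c]
        starts[mask] = lo + rng.integers(0, (hi - lo) - lengths[mask] + 1)
    peaks = [
        Peak(chroms[ci], int(s), int(s + ln), name=f"random_{i}")
        for i, (ci, s, ln) in enumerate(zip(chrom_idx, starts, lengths))
    ]
    return PeakSet(label=f"random({template.label})", peaks=peaks)


# ---------------------------------------------------------------------------
# enrichment stratification
# ---------------------------------------------------------------------------

def stratify_by_enrichment(
    peaks: PeakSet, threshold: float = 0.2
) -> tuple[PeakSet, PeakSet]:
    """Split a peak set into low/high relative-enrichment strata.

    "Relative enrichment" is each peak's enrichment divided by the set maximum
    (range (0, 1]); peaks with relative enrichment < threshold go to the low
    stratum, >= threshold (ties included) to the high stratum.
    """
    if len(peaks) == 0:
        return PeakSet(f"{peaks.label}|low"), PeakSet(f"{peaks.label}|high")
    vals = peaks.enrichments()
    vmax = vals.max()
    if vmax <= 0:
        raise ValidationError(
            f"stratify_by_enrichment: max enrichment is {vmax}, cannot rescale"
        )
    rel = vals / vmax
    low = [p for p, r in zip(peaks.peaks, rel) if r < threshold]
    high = [p for p, r in zip(peaks.peaks, rel) if r >= threshold]
    return (PeakSet(f"{peaks.label}|low", low), PeakSet(f"{peaks.label}|high", high))
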