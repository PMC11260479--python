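"""Interval-averaged minor allele frequency (MAF).

Binding sites that tolerate less sequence variation show depressed average MAF;
this module aggregates a SNP table over a peak set.  "Average MAF of a peak
set" is, by default, the mean over dbSNP-record positions falling inside peaks
(non-variant bases contribute nothing).  A second mode treats every covered
base as an observation with non-SNP bases at MAF 0, which changes the scale
drastically; it is provided for sensitivity checks only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .intervals import PeakSet
from .util import normalize_chromosome

__all__ = ["SnpTable", "load_snp_table", "write_snp_table", "mean_maf_over_peaks",
           "MafResult"]


@dataclass
class SnpTable:
    """SNP positions (0-based) with folded minor allele frequencies.

    Stored as per-chromosome sorted position/maf arrays; duplicate positions
    are collapsed keeping the maximum MAF (with a warning).
    """

    positions: dict[str, np.ndarray]
    mafs: dict[str, np.ndarray]

    @classmethod
    def from_records(cls, chroms, positions, mafs) -> "SnpTable":
        df = pd.DataFrame({
            "chrom": list(chroms),
            "pos": np.asarray(positions, dtype=np.int64),
            "maf": np.asarray(mafs, dtype=float),
        })
        if ((df["maf"] < 0) | (df["maf"] > 0.5)).any():
            bad = df.index[(df["maf"] < 0) | (df["maf"] > 0.5)][0]
            raise ValidationError(f"SNP record {bad}: folded MAF outside [0, 0.5]")
        pos_d: dict[str, np.ndarray] = {}
        maf_d: dict[str, np.ndarray] = {}
        n_dup = 0
        for chrom, sub in df.groupby("chrom", sort=True):
            n_dup += int(sub["pos"].duplicated().sum())
            sub = (sub.sort_values(["pos", "maf"])
                      .drop_duplicates("pos", keep="last"))  # keep max maf
            pos_d[str(chrom)] = sub["pos"].to_numpy()
            maf_d[str(chrom)] = sub["maf"].to_numpy()
        if n_dup:
            warnings.warn(f"SnpTable: collapsed {n_dup} duplicate position(s), "
                          "keeping the maximum MAF", stacklevel=3)
        return cls(positions=pos_d, mafs=maf_d)

    def __len__(self) -> int:
        return sum(p.size for p in self.positions.values())

    def to_dataframe(self) -> pd.DataFrame:
        frames = [pd.DataFrame({"chrom": c, "pos": self.positions[c],
                                "maf": self.mafs[c]})
                  for c in sorted(self.positions)]
        return pd.concat(frames, ignore_index=True) if frames else \
            pd.DataFrame(columns=["chrom", "pos", "maf"])


@dataclass(frozen=True)
class MafResult:
    mean: float
    sem: float
    n_snps: int


def _fold(freq: np.ndarray) -> np.ndarray:
    return np.minimum(freq, 1.0 - freq)


def load_snp_table(
    path,
    maf_column_or_info_key: str = "maf",
    *,
    fold: bool = True,
    strip_prefix: str = "chr",
    one_based: bool = False,
) -> SnpTable:
    """Load a SNP table from TSV (``chrom pos maf``, 0-based by default) or a
    VCF (extension .vcf/.vcf.gz; CHROM/POS plus an INFO frequency key, 1-based
    positions shifted on load).

    With ``fold=True`` (default) the frequency column may be an allele
    frequency in [0, 1]; it is folded to the minor allele, min(f, 1 - f).
    Records with a missing frequency are dropped and counted.
    """
    spath = str(path)
    if spath.endswith((".vcf", ".vcf.gz")):
        return _load_vcf(spath, maf_column_or_info_key, fold=fold,
                         strip_prefix=strip_prefix)
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty SNP table") from exc
    if maf_column_or_info_key not in df.columns:
        raise ParseError(f"{path}: no column {maf_column_or_info_key!r} "
                         f"(have {list(df.columns)})")
    freq = pd.to_numeric(df[maf_column_or_info_key], errors="coerce")
    n_missing = int(freq.isna().sum())
    if n_missing:
        warnings.warn(f"{path}: dropped {n_missing} record(s) without a frequency",
                      stacklevel=2)
    keep = ~freq.isna()
    df, freq = df[keep], freq[keep].to_numpy(dtype=float)
    if df.empty:
        raise ValidationError(f"{path}: no parseable SNP records")
    if ((freq < 0) | (freq > 1)).any():
        line = int(np.flatnonzero((freq < 0) | (freq > 1))[0]) + 2
        raise ValidationError(f"{path}: frequency outside [0, 1] at line {line}")
    maf = _fold(freq) if fold else freq
    chroms = df.iloc[:, 0].map(lambda c: normalize_chromosome(c, strip_prefix))
    pos = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if pos.isna().any():
        line = int(np.flatnonzero(pos.isna().to_numpy())[0]) + 2
        raise ParseError(f"{path}: non-numeric position at line {line}")
    pos = pos.astype(np.int64) - (1 if one_based else 0)
    return SnpTable.from_records(chroms, pos, maf)


def _load_vcf(path: str, info_key: str, *, fold: bool, strip_prefix: str) -> SnpTable:
    from cyvcf2 import VCF

    chroms: list[str] = []
    positions: list[int] = []
    freqs: list[float] = []
    n_missing = 0
    for v in VCF(path):
        f = v.INFO.get(info_key)
        if f is None:
            n_missing += 1
            continue
        if isinstance(f, (tuple, list)):
            f = f[0]
        f = float(f)
        if f < 0 or f > 1:
            raise ValidationError(f"{path}: {v.CHROM}:{v.POS}: frequency {f} "
                                  "outside [0, 1]")
        chroms.append(normalize_chromosome(v.CHROM, strip_prefix))
        positions.append(v.POS - 1)  # VCF is 1-based
        freqs.append(f)
    if n_missing:
        warnings.warn(f"{path}: dropped {n_missing} record(s) without INFO/{info_key}",
                      stacklevel=3)
    if not positions:
        raise ValidationError(f"{path}: no parseable SNP records")
    maf = _fold(np.asarray(freqs)) if fold else np.asarray(freqs)
    return SnpTable.from_records(chroms, positions, maf)


def write_snp_table(snps: SnpTable, path) -> None:
    snps.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.8g")


def mean_maf_over_peaks(
    peaks: PeakSet, snps: SnpTable, *, mode: str = "snp_positions"
) -> MafResult:
    """Mean +/- SEM of MAF over a peak set.

    ``mode="snp_positions"`` (default): observations are the SNP records whose
    position falls in any peak (half-open intervals; a SNP covered by several
    overlapping peaks counts once).  ``mode="all_bases"``: every base covered
    by the peak-set union is an observation, non-SNP bases at MAF 0.
    """
    if mode not in ("snp_positions", "all_bases"):
        raise ValueError(f"mean_maf_over_peaks: unknown mode {mode!r}")
    if len(peaks) == 0:
        raise ValidationError("mean_maf_over_peaks: empty peak set")
    picked: list[np.ndarray] = []
    union_bp = 0
    df = peaks.to_dataframe()
    for chrom, sub in df.groupby("chrom", sort=True):
        # union of half-open intervals (overlapping peaks must not double count)
        ivs = sorted(zip(sub["start"], sub["end"]))
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        pos = snps.positions.get(str(chrom))
        for s, e in merged:
            union_bp += e - s
            if pos is None:
                continue
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="left")
            if hi > lo:
                picked.append(snps.mafs[str(chrom)][lo:hi])
    vals = np.concatenate(picked) if picked else np.empty(0)
    if vals.size == 0:
        raise ValidationError(
            f"mean_maf_over_peaks({peaks.label!r}): no SNP inside any of the "
            f"{len(peaks)} peaks ({union_bp} bp covered)"
        )
    if mode == "snp_positions":
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan
        return MafResult(mean=mean, sem=sem, n_snps=vals.size)
    # all_bases: N = union bp, sum/sumsq from SNP values, the rest are zeros
    n = union_bp
    total = float(vals.sum())
    mean = total / n
    var = (float((vals ** 2).sum()) - n * mean ** 2) / (n - 1) if n > 1 else math.nan
    sem = math.sqrt(max(var, 0.0) / n) if n > 1 else math.nan
    return MafResult(mean=mean, sem=sem, n_snps=vals.size)
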