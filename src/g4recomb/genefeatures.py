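"""Genomic-feature assignment of peaks and gene-set essentiality averaging.

A peak is annotated by the feature its *center* falls in (ChIPseeker-like
convention — any-overlap conventions shift the printed percentages), resolved
by a priority order when annotations overlap: promoter > 5'UTR > 3'UTR > CDS >
intron > intergenic.  The promoter is a derived window around the TSS,
(2000 bp upstream, 500 bp downstream) by default.

Gene essentiality uses CRISPR scores (average log2 fold change of sgRNA
abundance in knockout screens; lower = more essential): the mean score of the
genes a peak set occupies distinguishes binding to essential versus
dispensable portions of the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ParseError, ValidationError
from .intervals import Peak, PeakSet
from .util import normalize_chromosome

__all__ = [
    "Gene",
    "GeneModel",
    "GeneScoreTable",
    "DEFAULT_PRIORITY",
    "assign_feature",
    "feature_distribution",
    "genes_occupied",
    "mean_gene_score",
    "feature_territory",
    "load_gene_model",
    "load_gene_scores",
]

FEATURES = ("promoter", "utr5", "utr3", "cds", "intron", "intergenic")
DEFAULT_PRIORITY = ("promoter", "utr5", "utr3", "cds", "intron")
BLOCK_FEATURES = ("utr5", "cds", "intron", "utr3")


@dataclass
class Gene:
    """A gene with typed feature blocks.

    ``tss``/``tes`` are 0-based positions of the first/last transcribed base;
    for a minus-strand gene the TSS is the higher coordinate.  ``blocks`` are
    half-open ``(feature, start, end)`` intervals inside the gene span.
    """

    name: str
    chromosome: str
    strand: str
    tss: int
    tes: int
    blocks: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.name}: strand must be + or -")
        lo, hi = self.body_span
        for feat, s, e in self.blocks:
            if feat not in BLOCK_FEATURES:
                raise ValidationError(f"gene {self.name}: unknown block feature {feat!r}")
            if s >= e or s < lo or e > hi:
                raise ValidationError(
                    f"gene {self.name}: block {feat} [{s},{e}) outside gene span [{lo},{hi})"
                )

    @property
    def body_span(self) -> tuple[int, int]:
        """Half-open genomic span of the transcribed region."""
        return min(self.tss, self.tes), max(self.tss, self.tes) + 1

    def promoter_span(self, window: tuple[int, int]) -> tuple[int, int]:
        """Half-open promoter window: ``window[0]`` bp upstream of the TSS and
        ``window[1]`` bp downstream (in transcription direction), TSS included."""
        up, down = window
        if self.strand == "+":
            return self.tss - up, self.tss + down
        return self.tss - down + 1, self.tss + up + 1


@dataclass
class GeneModel:
    genes: list[Gene]
    promoter_window: tuple[int, int] = (2000, 500)
    _trees: dict[str, IntervalTree] | None = field(default=None, repr=False)

    def feature_trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval tree of (feature, gene-name) annotations,
        promoters included; built lazily, the model is treated as immutable."""
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for g in self.genes:
                tree = trees.setdefault(g.chromosome, IntervalTree())
                ps, pe = g.promoter_span(self.promoter_window)
                if ps < pe:
                    tree.addi(ps, pe, ("promoter", g.name))
                for feat, s, e in g.blocks:
                    tree.addi(s, e, (feat, g.name))
            self._trees = trees
        return self._trees


@dataclass
class GeneScoreTable:
    """gene name -> CRISPR score (lower = more essential)."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        for g, s in self.scores.items():
            if not math.isfinite(s):
                raise ValidationError(f"gene {g}: non-finite score")

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def assign_feature(
    peak: Peak,
    model: GeneModel,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> str:
    """Feature label of the peak center, resolved by priority when the center
    hits several annotations (overlapping genes); 'intergenic' if none."""
    tree = model.feature_trees().get(peak.chromosome)
    if tree is None:
        return "intergenic"
    c = peak.center
    hits = {iv.data[0] for iv in tree.overlap(c, c + 1)}
    for feat in priority:
        if feat in hits:
            return feat
    return "intergenic"


def feature_distribution(
    peaks: PeakSet,
    model: GeneModel,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> dict[str, float]:
    """Proportion of peaks per feature class (sums to 1)."""
    if len(peaks) == 0:
        raise ValidationError("feature_distribution: empty peak set")
    counts = {f: 0 for f in (*priority, "intergenic")}
    for p in peaks:
        counts[assign_feature(p, model, priority)] += 1
    n = len(peaks)
    return {f: c / n for f, c in counts.items()}


def genes_occupied(peaks: PeakSet, model: GeneModel) -> set[str]:
    """Genes whose span (body union promoter window) overlaps >= 1 peak."""
    trees = peaks.interval_trees()
    out: set[str] = set()
    for g in model.genes:
        tree = trees.get(g.chromosome)
        if tree is None:
            continue
        bs, be = g.body_span
        ps, pe = g.promoter_span(model.promoter_window)
        lo, hi = min(bs, ps), max(be, pe)
        if tree.overlap(lo, hi):
            out.add(g.name)
    return out


def mean_gene_score(
    genes: Iterable[str], scores: GeneScoreTable
) -> tuple[float, float, int]:
    """Mean, SEM and count of CRISPR scores over the genes present in the
    table; unscored genes are simply not counted."""
    vals = np.array([scores.scores[g] for g in genes if g in scores.scores])
    if vals.size == 0:
        raise ValidationError("mean_gene_score: none of the genes has a score")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan
    return mean, sem, int(vals.size)


# ---------------------------------------------------------------------------
# priority-resolved territory (used by the synthetic generator and for audits)
# ---------------------------------------------------------------------------

def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """a \\ b for merged, sorted interval lists."""
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def feature_territory(
    model: GeneModel,
    chrom_lengths: Mapping[str, int],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Partition each chromosome into the bp where :func:`assign_feature`
    would return each feature.  Higher-priority features shadow lower ones,
    so the returned intervals are disjoint and cover [0, length)."""
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {
        c: {f: [] for f in priority} for c in chrom_lengths
    }
    for g in model.genes:
        if g.chromosome not in raw:
            continue
        ps, pe = g.promoter_span(model.promoter_window)
        raw[g.chromosome]["promoter"].append((max(ps, 0), pe))
        for feat, s, e in g.blocks:
            if feat in raw[g.chromosome]:
                raw[g.chromosome][feat].append((s, e))
    out: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for chrom, length in chrom_lengths.items():
        taken: list[tuple[int, int]] = []
        per_feat: dict[str, list[tuple[int, int]]] = {}
        for feat in priority:
            merged = _merge(raw[chrom][feat])
            merged = [(max(s, 0), min(e, length)) for s, e in merged if min(e, length) > max(s, 0)]
            resolved = _subtract(merged, taken)
            per_feat[feat] = resolved
            taken = _merge(taken + resolved)
        per_feat["intergenic"] = _subtract([(0, length)], taken)
        out[chrom] = per_feat
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_gene_model(
    genes_path,
    blocks_path=None,
    *,
    promoter_window: tuple[int, int] = (2000, 500),
    strip_prefix: str = "chr",
) -> GeneModel:
    """Load a gene model.

    Two layouts are supported: a simple pair of TSVs (``name chrom strand tss
    tes`` plus a block table ``name feature start end``), or a single BED12
    file (``blocks_path=None`` and extension .bed/.bed12) from which
    5'UTR/CDS/intron/3'UTR blocks are derived using thickStart/thickEnd.
    """
    spath = str(genes_path)
    if blocks_path is None and spath.endswith((".bed", ".bed12")):
        return _load_bed12(spath, promoter_window=promoter_window,
                           strip_prefix=strip_prefix)
    genes_df = pd.read_csv(genes_path, sep=r"\s+")
    need = {"name", "chrom", "strand", "tss", "tes"}
    if not need.issubset(genes_df.columns):
        raise ParseError(f"{genes_path}: need columns {sorted(need)}")
    blocks: dict[str, list[tuple[str, int, int]]] = {}
    if blocks_path is not None:
        blocks_df = pd.read_csv(blocks_path, sep=r"\s+")
        bneed = {"name", "feature", "start", "end"}
        if not bneed.issubset(blocks_df.columns):
            raise ParseError(f"{blocks_path}: need columns {sorted(bneed)}")
        for row in blocks_df.itertuples(index=False):
            blocks.setdefault(str(row.name), []).append(
                (str(row.feature), int(row.start), int(row.end)))
    genes = [
        Gene(
            name=str(r.name),
            chromosome=normalize_chromosome(r.chrom, strip_prefix),
            strand=str(r.strand),
            tss=int(r.tss),
            tes=int(r.tes),
            blocks=blocks.get(str(r.name), []),
        )
        for r in genes_df.itertuples(index=False)
    ]
    return GeneModel(genes=genes, promoter_window=promoter_window)


def _load_bed12(path: str, *, promoter_window, strip_prefix) -> GeneModel:
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom = normalize_chromosome(f[0], strip_prefix)
            start, end = int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(offs, sizes)]
            blocks: list[tuple[str, int, int]] = []
            left_utr = "utr5" if strand == "+" else "utr3"
            right_utr = "utr3" if strand == "+" else "utr5"
            for es, ee in exons:
                for fs, fe, feat in ((es, min(ee, thick_s), left_utr),
                                     (max(es, thick_s), min(ee, thick_e), "cds"),
                                     (max(es, thick_e), ee, right_utr)):
                    if fs < fe:
                        blocks.append((feat, fs, fe))
            for (_, e1), (s2, _) in zip(exons, exons[1:]):
                if e1 < s2:
                    blocks.append(("intron", e1, s2))
            tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
            genes.append(Gene(name=name, chromosome=chrom, strand=strand,
                              tss=tss, tes=tes, blocks=blocks))
    return GeneModel(genes=genes, promoter_window=promoter_window)


def load_gene_scores(path) -> GeneScoreTable:
    """Score table TSV with columns ``gene`` and ``score``."""
    df = pd.read_csv(path, sep=r"\s+")
    if not {"gene", "score"}.issubset(df.columns):
        raise ParseError(f"{path}: need columns ['gene', 'score']")
    if df["gene"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene names")
    return GeneScoreTable(scores=dict(zip(df["gene"].astype(str),
                                          df["score"].astype(float))))


def write_gene_model(model: GeneModel, genes_path, blocks_path) -> None:
    gdf = pd.DataFrame(
        [(g.name, g.chromosome, g.strand, g.tss, g.tes) for g in model.genes],
        columns=["name", "chrom", "strand", "tss", "tes"],
    )
    gdf.to_csv(genes_path, sep="\t", index=False)
    rows = [(g.name, feat, s, e) for g in model.genes for feat, s, e in g.blocks]
    pd.DataFrame(rows, columns=["name", "feature", "start", "end"]).to_csv(
        blocks_path, sep="\t", index=False)


def write_gene_scores(table: GeneScoreTable, path) -> None:
    pd.DataFrame(sorted(table.scores.items()), columns=["gene", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")
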