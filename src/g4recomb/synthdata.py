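"""Synthetic toy genomes with the statistical structure the analysis assumes.

Every generator is seeded, bit-reproducible, and returns a machine-readable
*truth record* (a JSON-serializable dict) from which the expected value of
each downstream statistic can be computed analytically or by brute force:

* a piecewise recombination landscape with planted hotspots (narrow, strongly
  elevated rate, emulating PRDM9-defined hotspots) and coldspots (broad,
  depressed rate, emulating the low-recombination domains where G4/YY1 peaks
  concentrate),
* peak sets with a tunable preference for coldspot placement, or linked to an
  existing set (to create overlapping datasets),
* Poisson-placed SNPs whose minor allele frequencies are drawn from truncated
  normals per landscape class — recovery tests need known class means, not a
  realistic site-frequency spectrum,
* per-chromosome signal tracks with a planted central dip or bump at every
  peak plus Gaussian step noise (the nucleosome-depletion metaplot shape),
* non-overlapping gene models with typed blocks and essentiality-class CRISPR
  scores,
* A/T background sequences with planted G4 motifs at known counts.

One global seed fans out to independent per-generator streams so adding a
generator never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .genmap import GeneticMap, genome_average_rate
from .genefeatures import Gene, GeneModel, GeneScoreTable, feature_territory
from .intervals import Peak, PeakSet
from .signal_profiles import SignalTrack
from .variant_maf import SnpTable

__all__ = [
    "LandscapeSpec",
    "PeakPlacementSpec",
    "GeneGeometry",
    "make_genetic_map",
    "make_peaks",
    "make_linked_peaks",
    "make_snps",
    "make_tracks",
    "make_gene_model_and_scores",
    "make_feature_peaks",
    "make_g4_sequences",
    "G4_MOTIF",
]

# stream tags keeping per-generator RNGs independent under one global seed
_STREAMS = {"landscape": 11, "peaks": 23, "linked": 29, "snps": 37,
            "tracks": 41, "genes": 53, "featpeaks": 59, "g4seq": 67}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([_STREAMS[stream], int(seed)]))


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

@dataclass
class LandscapeSpec:
    """Recombination-landscape blueprint.

    Defaults describe the toy study genome: 10 Mb over two chromosomes, a
    background of 1.2 cM/Mb (about the human genome-wide average), 30 narrow
    hotspots at 10x background and 20 broad coldspots at 0.1x background
    (roughly 10% of the genome lies in a coldspot).
    """

    chromosomes: Sequence[tuple[str, int]] = (("1", 5_000_000), ("2", 5_000_000))
    background_rate: float = 1.2
    n_hotspots: int = 30
    hotspot_width: int = 2_000
    hotspot_multiplier: float = 10.0
    n_coldspots: int = 20
    coldspot_width: int = 50_000
    coldspot_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, length in self.chromosomes:
            if max(self.hotspot_width, self.coldspot_width) >= length:
                raise ValidationError(f"chromosome {name}: planted width >= length")
        if self.hotspot_multiplier <= 1:
            raise ValidationError("hotspot_multiplier must be > 1")
        if not (0 <= self.coldspot_fraction < 1):
            raise ValidationError("coldspot_fraction must be in [0, 1)")


def make_genetic_map(spec: LandscapeSpec) -> tuple[dict[str, GeneticMap], dict]:
    """Build the planted piecewise map; returns (maps, truth).

    Planted regions are drawn without overlap (rejection sampling, capped);
    the truth record lists every region with its class and rate, the exact
    genome-average rate, and the per-class bp shares.
    """
    rng = _rng(spec.seed, "landscape")
    labels = [c[0] for c in spec.chromosomes]
    lengths = {c[0]: int(c[1]) for c in spec.chromosomes}
    total = sum(lengths.values())
    probs = np.array([lengths[c] for c in labels], dtype=float) / total

    regions: list[dict] = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in labels}
    plan = [("hotspot", spec.hotspot_width,
             spec.background_rate * spec.hotspot_multiplier)] * spec.n_hotspots
    plan += [("coldspot", spec.coldspot_width,
              spec.background_rate * spec.coldspot_fraction)] * spec.n_coldspots
    for cls, width, rate in plan:
        for _ in range(1000):
            chrom = labels[rng.choice(len(labels), p=probs)]
            start = int(rng.integers(0, lengths[chrom] - width + 1))
            end = start + width
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                regions.append({"chrom": chrom, "start": start, "end": end,
                                "class": cls, "rate": rate})
                break
        else:
            raise ValidationError(
                f"make_genetic_map: could not place a {cls} without overlap"
            )

    maps: dict[str, GeneticMap] = {}
    for chrom in labels:
        length = lengths[chrom]
        regs = sorted((r["start"], r["end"], r["rate"])
                      for r in regions if r["chrom"] == chrom)
        pos = [0]
        rate = []
        cursor_rate = spec.background_rate
        for s, e, r in regs:
            if s > pos[-1]:
                rate.append(spec.background_rate)
                pos.append(s)
            rate.append(r)
            pos.append(e)
        if pos[-1] < length:
            rate.append(spec.background_rate)
            pos.append(length)
        rate.append(0.0)  # last anchor carries no forward interval
        pos_arr = np.array(pos, dtype=np.int64)
        rate_arr = np.array(rate, dtype=float)
        cum = np.concatenate([[0.0],
                              np.cumsum(rate_arr[:-1] * np.diff(pos_arr) / 1e6)])
        maps[chrom] = GeneticMap(chromosome=chrom, positions=pos_arr,
                                 rates=rate_arr, cum_cm=cum)

    cold_bp = sum(r["end"] - r["start"] for r in regions if r["class"] == "coldspot")
    hot_bp = sum(r["end"] - r["start"] for r in regions if r["class"] == "hotspot")
    truth = {
        "spec": {**asdict(spec), "chromosomes": [[c, int(n)] for c, n in spec.chromosomes]},
        "chromosome_lengths": lengths,
        "regions": regions,
        "genome_average_rate": genome_average_rate(maps),
        "cold_bp": cold_bp,
        "hot_bp": hot_bp,
        "cold_bp_share": cold_bp / total,
        "hot_bp_share": hot_bp / total,
        "total_bp": total,
    }
    return maps, truth


def _class_lookup(truth: dict):
    """Return a function position -> landscape class, from region boundaries."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in truth["chromosome_lengths"]:
        regs = sorted((r["start"], r["end"], r["class"])
                      for r in truth["regions"] if r["chrom"] == chrom)
        starts = np.array([r[0] for r in regs], dtype=np.int64)
        ends = np.array([r[1] for r in regs], dtype=np.int64)
        by_chrom[chrom] = (starts, ends, [r[2] for r in regs])

    def lookup(chrom: str, position: int) -> str:
        starts, ends, classes = by_chrom[chrom]
        i = int(np.searchsorted(starts, position, side="right")) - 1
        if i >= 0 and position < ends[i]:
            return classes[i]
        return "background"

    return lookup


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

@dataclass
class PeakPlacementSpec:
    """Peak-placement blueprint.

    ``cold_preference`` is the probability that a peak center is drawn from
    coldspot bp rather than uniformly from the whole genome (so the expected
    coldspot fraction is ``p + (1 - p) * cold_bp_share``).  Lengths are
    normal(mean, sd) clipped at ``min_length``; enrichments are lognormal,
    emulating the long-tailed signalValue column of peak callers.
    """

    n_peaks: int = 500
    length_mean: float = 300.0
    length_sd: float = 100.0
    min_length: int = 50
    cold_preference: float = 0.8
    enrichment_mu: float = 1.0      # log-scale mean
    enrichment_sigma: float = 0.8   # log-scale sd
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cold_preference <= 1.0):
            raise ValidationError("cold_preference must be in [0, 1]")
        if self.length_mean <= 0 or self.min_length <= 0:
            raise ValidationError("peak lengths must be positive")


def make_peaks(spec: PeakPlacementSpec, landscape_truth: dict,
               *, label: str = "synthetic") -> tuple[PeakSet, dict]:
    """Place peaks with the stated coldspot preference; returns (peaks, truth).

    The truth record carries each peak's realized landscape class (from its
    final center position) and the analytic expected coldspot fraction.
    """
    rng = _rng(spec.seed, "peaks")
    lengths_by_chrom = landscape_truth["chromosome_lengths"]
    labels = sorted(lengths_by_chrom)
    chrom_probs = np.array([lengths_by_chrom[c] for c in labels], dtype=float)
    chrom_probs /= chrom_probs.sum()
    cold = [(r["chrom"], r["start"], r["end"])
            for r in landscape_truth["regions"] if r["class"] == "coldspot"]
    cold_bp = np.array([e - s for _, s, e in cold], dtype=float)
    if spec.cold_preference > 0 and not cold:
        raise ValidationError("make_peaks: cold_preference > 0 but no coldspots planted")
    lookup = _class_lookup(landscape_truth)

    peaks: list[Peak] = []
    classes: list[str] = []
    use_cold = rng.random(spec.n_peaks) < spec.cold_preference
    lengths = np.maximum(
        np.rint(rng.normal(spec.length_mean, spec.length_sd, spec.n_peaks)),
        spec.min_length).astype(np.int64)
    enrich = rng.lognormal(spec.enrichment_mu, spec.enrichment_sigma, spec.n_peaks)
    for i in range(spec.n_peaks):
        if use_cold[i]:
            j = rng.choice(len(cold), p=cold_bp / cold_bp.sum())
            chrom, s, e = cold[j]
            center = int(rng.integers(s, e))
        else:
            chrom = labels[rng.choice(len(labels), p=chrom_probs)]
            center = int(rng.integers(0, lengths_by_chrom[chrom]))
        half = int(lengths[i]) // 2
        start = max(0, min(center - half, lengths_by_chrom[chrom] - int(lengths[i])))
        peaks.append(Peak(chrom, start, start + int(lengths[i]),
                          name=f"{label}_{i}", enrichment=float(enrich[i])))
        classes.append(lookup(chrom, peaks[-1].center))
    cold_share = landscape_truth["cold_bp_share"]
    truth = {
        "spec": asdict(spec),
        "classes": classes,
        "expected_cold_fraction":
            spec.cold_preference + (1 - spec.cold_preference) * cold_share,
        "realized_cold_fraction": classes.count("coldspot") / max(len(classes), 1),
    }
    return PeakSet(label=label, peaks=peaks), truth


def make_linked_peaks(
    template: PeakSet,
    landscape_truth: dict,
    n: int,
    linked_fraction: float,
    *,
    jitter: int = 100,
    length_mean: float = 300.0,
    length_sd: float = 100.0,
    min_length: int = 50,
    seed: int = 0,
    label: str = "linked",
) -> tuple[PeakSet, dict]:
    """Peaks that overlap a template set with probability ``linked_fraction``.

    Linked peaks center within ``jitter`` bp of a random template peak center
    (creating overlapping datasets, e.g. G4 peaks co-occurring with a binding
    protein's peaks); the rest are uniform background placements.
    """
    if not (0 <= linked_fraction <= 1):
        raise ValidationError("linked_fraction must be in [0, 1]")
    if len(template) == 0:
        raise ValidationError("make_linked_peaks: empty template")
    rng = _rng(seed, "linked")
    lengths_by_chrom = landscape_truth["chromosome_lengths"]
    labels = sorted(lengths_by_chrom)
    chrom_probs = np.array([lengths_by_chrom[c] for c in labels], dtype=float)
    chrom_probs /= chrom_probs.sum()
    tpl = template.peaks
    linked = rng.random(n) < linked_fraction
    lengths = np.maximum(np.rint(rng.normal(length_mean, length_sd, n)),
                         min_length).astype(np.int64)
    peaks: list[Peak] = []
    for i in range(n):
        if linked[i]:
            t = tpl[rng.integers(0, len(tpl))]
            chrom = t.chromosome
            center = t.center + int(rng.integers(-jitter, jitter + 1))
        else:
            chrom = labels[rng.choice(len(labels), p=chrom_probs)]
            center = int(rng.integers(0, lengths_by_chrom[chrom]))
        half = int(lengths[i]) // 2
        start = max(0, min(center - half, lengths_by_chrom[chrom] - int(lengths[i])))
        peaks.append(Peak(chrom, start, start + int(lengths[i]), name=f"{label}_{i}"))
    truth = {"linked": linked.tolist(), "linked_fraction": linked_fraction,
             "jitter": jitter}
    return PeakSet(label=label, peaks=peaks), truth


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

def make_snps(
    density: float,
    maf_by_class: Mapping[str, tuple[float, float]],
    landscape_truth: dict,
    seed: int = 0,
    *,
    maf_bounds: tuple[float, float] = (0.01, 0.5),
) -> tuple[SnpTable, dict]:
    """Poisson-placed SNPs with class-dependent truncated-normal MAFs.

    ``maf_by_class`` maps each landscape class (``coldspot``/``hotspot``/
    ``background``) to (mu, sigma); draws are truncated to ``maf_bounds``.
    The truth record stores, per class, the planted (mu, sigma) and the exact
    truncated-normal mean the recovery tests compare against.
    """
    if density < 0:
        raise ValidationError("make_snps: density must be >= 0")
    for cls, (mu, sigma) in maf_by_class.items():
        if not (0 < mu < 0.5) or sigma < 0:
            raise ValidationError(f"make_snps: invalid (mu, sigma) for class {cls!r}")
    rng = _rng(seed, "snps")
    lookup = _class_lookup(landscape_truth)
    lo, hi = maf_bounds
    chroms: list[str] = []
    positions: list[int] = []
    mafs: list[float] = []
    class_of: list[str] = []
    for chrom, length in sorted(landscape_truth["chromosome_lengths"].items()):
        n = int(rng.poisson(density * length))
        if n == 0:
            continue
        pos = np.unique(rng.integers(0, length, size=n))  # collisions collapse
        cls = [lookup(chrom, int(p)) for p in pos]
        for p, c in zip(pos, cls):
            mu, sigma = maf_by_class[c]
            if sigma == 0:
                maf = mu
            else:
                a, b = (lo - mu) / sigma, (hi - mu) / sigma
                maf = float(stats.truncnorm.rvs(a, b, loc=mu, scale=sigma,
                                                random_state=rng))
            chroms.append(chrom)
            positions.append(int(p))
            mafs.append(maf)
            class_of.append(c)
    table = (SnpTable.from_records(chroms, positions, mafs)
             if positions else SnpTable(positions={}, mafs={}))
    truth_classes = {}
    for cls, (mu, sigma) in maf_by_class.items():
        if sigma == 0:
            trunc_mean = mu
        else:
            a, b = (lo - mu) / sigma, (hi - mu) / sigma
            trunc_mean = float(stats.truncnorm.mean(a, b, loc=mu, scale=sigma))
        truth_classes[cls] = {"mu": mu, "sigma": sigma, "truncated_mean": trunc_mean}
    truth = {"density": density, "maf_bounds": list(maf_bounds),
             "classes": truth_classes,
             "snp_class": class_of, "n_snps": len(positions)}
    return table, truth


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

def make_tracks(
    peaks: PeakSet,
    chrom_lengths: Mapping[str, int],
    *,
    shape: str = "dip",
    depth: float = 0.5,
    width: int = 500,
    noise_sd: float = 0.2,
    step: int = 50,
    baseline: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, SignalTrack], dict]:
    """Whole-chromosome step tracks: baseline plus a rectangular central dip
    (or bump) of the given depth/height and width at every peak center, with
    i.i.d. Gaussian noise per step."""
    if shape not in ("dip", "bump"):
        raise ValueError(f"make_tracks: unknown shape {shape!r}")
    rng = _rng(seed, "tracks")
    tracks: dict[str, SignalTrack] = {}
    half = width // 2
    centers_by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        centers_by_chrom.setdefault(p.chromosome, []).append(p.center)
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + step, length)
        values = np.full(starts.size, baseline, dtype=float)
        mids = starts + (ends - starts) // 2
        for c in centers_by_chrom.get(chrom, []):
            sel = (mids >= c - half) & (mids < c + half)
            values[sel] += -depth if shape == "dip" else depth
        if noise_sd > 0:
            values += rng.normal(0.0, noise_sd, values.size)
        tracks[chrom] = SignalTrack(chrom, starts, ends, values)
    truth = {"shape": shape, "depth": depth, "width": width,
             "noise_sd": noise_sd, "step": step, "baseline": baseline}
    return tracks, truth


# ---------------------------------------------------------------------------
# gene models and scores
# ---------------------------------------------------------------------------

@dataclass
class GeneGeometry:
    """Block layout of a synthetic gene (5' to 3'): 5'UTR, then ``n_cds_exons``
    CDS exons separated by introns, then 3'UTR.  The 800 bp 5'UTR leaves part
    of the 5'UTR outside the default (2000, 500) promoter window, so every
    feature class retains territory under the priority rule."""

    utr5: int = 800
    n_cds_exons: int = 3
    cds_exon: int = 500
    intron: int = 2000
    utr3: int = 300
    min_gap: int = 5000
    max_gap: int = 20000

    @property
    def gene_length(self) -> int:
        return (self.utr5 + self.n_cds_exons * self.cds_exon
                + (self.n_cds_exons - 1) * self.intron + self.utr3)


def make_gene_model_and_scores(
    n_genes: int,
    chrom_lengths: Mapping[str, int],
    *,
    geometry: GeneGeometry | None = None,
    essential_fraction: float = 0.3,
    score_mean_essential: float = -2.5,
    score_mean_neutral: float = 0.0,
    score_sd: float = 0.5,
    promoter_window: tuple[int, int] = (2000, 500),
    seed: int = 0,
) -> tuple[GeneModel, GeneScoreTable, dict]:
    """Pack non-overlapping genes along the chromosomes and draw CRISPR-like
    scores per essentiality class (essential genes score lower)."""
    geom = geometry or GeneGeometry()
    rng = _rng(seed, "genes")
    glen = geom.gene_length
    genes: list[Gene] = []
    chroms = sorted(chrom_lengths)
    per_chrom = {c: [] for c in chroms}
    # round-robin by genome position: walk each chromosome with random gaps
    idx = 0
    cursors = {c: geom.min_gap for c in chroms}
    exhausted: set[str] = set()
    while idx < n_genes and len(exhausted) < len(chroms):
        for chrom in chroms:
            if idx >= n_genes or chrom in exhausted:
                continue
            gap = int(rng.integers(geom.min_gap, geom.max_gap + 1))
            start = cursors[chrom] + gap
            if start + glen + geom.min_gap > chrom_lengths[chrom]:
                exhausted.add(chrom)
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            blocks: list[tuple[str, int, int]] = []
            cursor = start
            order = (["utr5"] + ["cds", "intron"] * (geom.n_cds_exons - 1)
                     + ["cds", "utr3"])
            sizes = {"utr5": geom.utr5, "cds": geom.cds_exon,
                     "intron": geom.intron, "utr3": geom.utr3}
            if strand == "-":
                order = order[::-1]
            for feat in order:
                blocks.append((feat, cursor, cursor + sizes[feat]))
                cursor += sizes[feat]
            end = cursor
            tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
            genes.append(Gene(name=f"gene_{idx}", chromosome=chrom, strand=strand,
                              tss=tss, tes=tes, blocks=blocks))
            per_chrom[chrom].append((start, end))
            cursors[chrom] = end
            idx += 1
    if idx < n_genes:
        raise ValidationError(
            f"make_gene_model_and_scores: only {idx}/{n_genes} genes fit the genome"
        )
    essential = rng.random(n_genes) < essential_fraction
    scores = {}
    for g, is_ess in zip(genes, essential):
        mu = score_mean_essential if is_ess else score_mean_neutral
        scores[g.name] = float(rng.normal(mu, score_sd))
    model = GeneModel(genes=genes, promoter_window=promoter_window)
    truth = {
        "geometry": asdict(geom),
        "essential": {g.name: bool(e) for g, e in zip(genes, essential)},
        "score_mean_essential": score_mean_essential,
        "score_mean_neutral": score_mean_neutral,
        "score_sd": score_sd,
        "essential_fraction": essential_fraction,
    }
    return model, GeneScoreTable(scores=scores), truth


def make_feature_peaks(
    model: GeneModel,
    chrom_lengths: Mapping[str, int],
    mixture: Mapping[str, float],
    n: int,
    *,
    peak_length: int = 200,
    seed: int = 0,
    label: str = "feature_peaks",
) -> tuple[PeakSet, dict]:
    """Peaks whose centers are planted in the priority-resolved territory of
    each feature class, with class probabilities given by ``mixture``.

    Because centers are sampled from the same partition :func:`assign_feature`
    resolves to, the realized feature distribution is an exact multinomial
    draw from ``mixture``.
    """
    feats = sorted(mixture)
    probs = np.array([mixture[f] for f in feats], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValidationError("make_feature_peaks: mixture must be a distribution")
    territory = feature_territory(model, chrom_lengths)
    pools: dict[str, list[tuple[str, int, int]]] = {f: [] for f in feats}
    for chrom, per_feat in territory.items():
        for f in feats:
            pools[f].extend((chrom, s, e) for s, e in per_feat.get(f, []))
    for f in feats:
        if mixture[f] > 0 and not pools[f]:
            raise ValidationError(f"make_feature_peaks: no territory for {f!r}")
    rng = _rng(seed, "featpeaks")
    half = peak_length // 2
    peaks: list[Peak] = []
    planted: list[str] = []
    draws = rng.choice(len(feats), size=n, p=probs)
    for i, fi in enumerate(draws):
        f = feats[fi]
        ivs = pools[f]
        weights = np.array([e - s for _, s, e in ivs], dtype=float)
        for _ in range(1000):
            j = rng.choice(len(ivs), p=weights / weights.sum())
            chrom, s, e = ivs[j]
            center = int(rng.integers(s, e))
            start = center - half
            if start >= 0 and start + peak_length <= chrom_lengths[chrom]:
                peaks.append(Peak(chrom, start, start + peak_length,
                                  name=f"{label}_{i}"))
                planted.append(f)
                break
        else:
            raise ValidationError(f"make_feature_peaks: cannot place a {f!r} peak")
    truth = {"mixture": dict(mixture), "planted": planted,
             "realized": {f: planted.count(f) / n for f in feats}}
    return PeakSet(label=label, peaks=peaks), truth


# ---------------------------------------------------------------------------
# G4 sequences
# ---------------------------------------------------------------------------

#: four G3 tracts with TTA loops — 21 bp, window-25 mean 36/25 = 1.44 >= 1.2
G4_MOTIF = "GGGTTAGGGTTAGGGTTAGGG"


def make_g4_sequences(
    planted_counts: Sequence[int],
    length: int = 2000,
    *,
    window: int = 25,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict]:
    """A/T background sequences, one per entry of ``planted_counts``, each with
    that many non-merging G4 motifs planted; returns ([(id, seq), ...], truth).

    Motifs are separated by more than one scan window of A/T so each planted
    motif yields exactly one merged prediction at default settings.
    """
    rng = _rng(seed, "g4seq")
    min_gap = window + 10
    records: list[tuple[str, str]] = []
    truth_seqs = []
    for i, k in enumerate(planted_counts):
        k = int(k)
        need = k * len(G4_MOTIF) + (k + 1) * min_gap
        if need > length:
            raise ValidationError(
                f"make_g4_sequences: {k} motifs need {need} bp > length {length}"
            )
        slack = length - need
        extra = rng.multinomial(slack, np.full(k + 1, 1 / (k + 1))) if k >= 0 else []
        gaps = [min_gap + int(x) for x in extra]
        background = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=length)
        seq = background.tobytes().decode("ascii")
        chunks: list[str] = []
        positions: list[int] = []
        cursor = 0
        for j in range(k):
            chunks.append(seq[cursor:cursor + gaps[j]])
            cursor += gaps[j]
            positions.append(sum(len(c) for c in chunks))
            chunks.append(G4_MOTIF)
            cursor += len(G4_MOTIF)
        chunks.append(seq[cursor:cursor + gaps[k]])
        final = "".join(chunks)
        records.append((f"site_{i}" if k else f"control_{i}", final))
        truth_seqs.append({"id": records[-1][0], "planted_count": k,
                           "positions": positions, "length": len(final)})
    truth = {"window": window, "motif": G4_MOTIF, "sequences": truth_seqs}
    return records, truth


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write([SeqRecord(Seq(s), id=name, description="") for name, s in records],
                str(path), "fasta")
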