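"""Config-driven orchestration of the full analysis reports.

A :class:`RunConfig` names the inputs (genetic map, labelled peak sets, SNP
table, signal track, gene model, scores, FASTA) and the handful of printed
parameter constants (5 kb profile flank, 10 kb distance flank, 50 bp bins,
0.2 relative-enrichment threshold, promoter window, G4Hunter settings).  Each
``run_*`` function loads what it needs, fails fast on a missing input, and
writes deterministic TSV/JSON artifacts that embed the seed, parameters and a
hash of the config, so identical config + seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthdata
from .errors import ValidationError
from .genmap import load_genetic_map, genome_average_rate, write_genetic_map
from .genefeatures import (feature_distribution, genes_occupied, load_gene_model,
                           load_gene_scores, mean_gene_score, write_gene_model,
                           write_gene_scores)
from .g4hunter import scan_fasta
from .intervals import (bounds_from_maps, complement_wa, overlap_wa, random_peaks,
                        read_peaks, stratify_by_enrichment, write_peaks)
from .recomb_annot import (center_rates, compare_to_null, flank_genetic_distance,
                           fraction_below_average, mean_center_rate, rate_profile)
from .signal_profiles import compute_matrix, read_bedgraph, write_bedgraph
from .variant_maf import load_snp_table, mean_maf_over_peaks, write_snp_table

__all__ = ["RunConfig", "run_heatmap_table", "run_coldspot_report",
           "run_profiles", "run_maf_features_scores", "simulate_dataset"]


@dataclass
class RunConfig:
    """Inputs and parameters for the pipeline runs; flat key=value file format
    (``peak_sets`` entries are ``peaks.<label>=<path>`` lines)."""

    map_path: str | None = None
    peak_sets: dict[str, str] = field(default_factory=dict)  # label -> path
    g4_peaks_path: str | None = None
    yy1_peaks_path: str | None = None
    snp_path: str | None = None
    track_path: str | None = None
    genes_path: str | None = None
    blocks_path: str | None = None
    scores_path: str | None = None
    fasta_path: str | None = None
    profile_flank: int = 5000
    distance_flank: int = 10000
    bin: int = 50
    enrichment_threshold: float = 0.2
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    g4_window: int = 25
    g4_threshold: float = 1.2
    null_n: int = 0          # 0 = match the observed set's size
    match_lengths: bool = True
    seed: int = 0
    outdir: str = "results"

    # -- serialization ------------------------------------------------------
    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "peak_sets":
                for label in sorted(v):
                    lines.append(f"peaks.{label}={v[label]}")
            elif v is not None:
                lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = cls()
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValidationError(f"{path}:{lineno}: expected key=value")
                key, value = (x.strip() for x in line.split("=", 1))
                if key.startswith("peaks."):
                    cfg.peak_sets[key[len("peaks."):]] = value
                    continue
                if not hasattr(cfg, key):
                    raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
                current = getattr(cfg, key)
                if isinstance(current, bool):
                    setattr(cfg, key, value.lower() in ("1", "true", "yes"))
                elif isinstance(current, int):
                    setattr(cfg, key, int(value))
                elif isinstance(current, float):
                    setattr(cfg, key, float(value))
                else:
                    setattr(cfg, key, value)
        return cfg

    @property
    def config_hash(self) -> str:
        # outdir is where results land, not an analytic input: exclude it so
        # the same analysis written to two directories hashes identically
        text = "\n".join(line for line in self.to_text().splitlines()
                         if not line.startswith("outdir="))
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def meta(self) -> dict:
        return {"seed": self.seed, "config_sha256": self.config_hash,
                "parameters": {
                    "profile_flank": self.profile_flank,
                    "distance_flank": self.distance_flank,
                    "bin": self.bin,
                    "enrichment_threshold": self.enrichment_threshold,
                    "promoter_window": [self.promoter_upstream,
                                        self.promoter_downstream],
                    "g4_window": self.g4_window,
                    "g4_threshold": self.g4_threshold,
                }}

    def _require(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if not path:
                raise ValidationError(f"config: {name} is required for this run")
            if not os.path.exists(path):
                raise FileNotFoundError(f"config: {name}={path} does not exist")


def _write_tsv(df: pd.DataFrame, path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={cfg.seed} config={cfg.config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _write_json(obj: dict, path, cfg: RunConfig) -> None:
    obj = {"meta": cfg.meta(), **obj}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _ttest_dict(cmp) -> dict:
    return {"t": cmp.t, "p": cmp.p,
            "mean_observed": cmp.mean_observed, "sem_observed": cmp.sem_observed,
            "mean_null": cmp.mean_null, "sem_null": cmp.sem_null,
            "n_observed": cmp.n_observed, "n_null": cmp.n_null}


# ---------------------------------------------------------------------------
# runs
# ---------------------------------------------------------------------------

def run_heatmap_table(cfg: RunConfig) -> pd.DataFrame:
    """Mean center recombination rate per labelled peak set, sorted ascending —
    the screening table ranking candidate binding proteins by how cold their
    binding sites are."""
    cfg._require("map_path")
    if not cfg.peak_sets:
        raise ValidationError("config: at least one peaks.<label>=<path> entry needed")
    maps = load_genetic_map(cfg.map_path)
    rows = []
    for label in sorted(cfg.peak_sets):
        path = cfg.peak_sets[label]
        if not os.path.exists(path):
            raise FileNotFoundError(f"config: peaks.{label}={path} does not exist")
        res = mean_center_rate(read_peaks(path, label=label), maps)
        rows.append((label, res.mean, res.sem, res.n_used, res.n_excluded))
    df = pd.DataFrame(rows, columns=["label", "mean_rate", "sem", "n_used",
                                     "n_excluded"])
    df = df.sort_values("mean_rate", kind="mergesort").reset_index(drop=True)
    os.makedirs(cfg.outdir, exist_ok=True)
    _write_tsv(df, os.path.join(cfg.outdir, "heatmap_table.tsv"), cfg)
    return df


def run_coldspot_report(cfg: RunConfig) -> dict:
    """The cold-spot analysis bundle: split G4-like peaks by overlap with the
    binding-protein set, compare group center rates; compare the protein set's
    flanking genetic distance against a seeded random-region null; compare
    low- vs high-enrichment strata; report the below-average fraction."""
    cfg._require("map_path", "g4_peaks_path", "yy1_peaks_path")
    maps = load_genetic_map(cfg.map_path)
    g4 = read_peaks(cfg.g4_peaks_path, label="g4")
    yy1 = read_peaks(cfg.yy1_peaks_path, label="yy1")

    overlap = overlap_wa(g4, yy1)
    nonoverlap = complement_wa(g4, yy1)
    if len(overlap) == 0:
        raise ValidationError("coldspot report: no G4 peak overlaps the protein set")
    rates_overlap, _ = center_rates(overlap, maps)
    rates_nonoverlap, _ = center_rates(nonoverlap, maps)
    overlap_vs_non = compare_to_null(rates_overlap, rates_nonoverlap)

    n_null = cfg.null_n or len(yy1)
    null = random_peaks(yy1, bounds_from_maps(maps), n_null,
                        match_lengths=cfg.match_lengths, seed=cfg.seed)
    dist_obs = flank_genetic_distance(yy1, maps, cfg.distance_flank)
    dist_null = flank_genetic_distance(null, maps, cfg.distance_flank)
    obs_vs_random = compare_to_null(dist_obs["cm"], dist_null["cm"])

    low, high = stratify_by_enrichment(yy1, cfg.enrichment_threshold)
    low_vs_high = compare_to_null(
        flank_genetic_distance(low, maps, cfg.distance_flank)["cm"],
        flank_genetic_distance(high, maps, cfg.distance_flank)["cm"],
    )

    report = {
        "genome_average_rate": genome_average_rate(maps),
        "fraction_below_average_overlap": fraction_below_average(overlap, maps),
        "fraction_below_average_protein": fraction_below_average(yy1, maps),
        "center_rate_overlap_vs_nonoverlap": _ttest_dict(overlap_vs_non),
        "flank_cm_protein_vs_random": _ttest_dict(obs_vs_random),
        "flank_cm_low_vs_high_enrichment": _ttest_dict(low_vs_high),
        "n_peaks": {"g4": len(g4), "protein": len(yy1),
                    "overlap": len(overlap), "nonoverlap": len(nonoverlap),
                    "null": len(null), "low": len(low), "high": len(high)},
    }
    os.makedirs(cfg.outdir, exist_ok=True)
    _write_json(report, os.path.join(cfg.outdir, "coldspot_report.json"), cfg)

    annot = dist_obs.copy()
    vals, in_map = [], []
    for chrom, sub in annot.groupby("chrom", sort=False):
        v, m = maps[chrom].rate_at_many(sub["center"].to_numpy())
        vals.append(v)
        in_map.append(m)
    annot["center_rate"] = np.concatenate(vals)
    annot["center_in_map"] = np.concatenate(in_map)
    _write_tsv(annot, os.path.join(cfg.outdir, "peak_annotation.tsv"), cfg)
    return report


def run_profiles(cfg: RunConfig) -> dict:
    """Rate metaplot around peak centers, and the computeMatrix-style signal
    matrix/aggregate when a bedGraph track is configured."""
    cfg._require("map_path", "yy1_peaks_path")
    maps = load_genetic_map(cfg.map_path)
    peaks = read_peaks(cfg.yy1_peaks_path, label="peaks")
    os.makedirs(cfg.outdir, exist_ok=True)
    prof = rate_profile(peaks, maps, flank=cfg.profile_flank, step=cfg.bin)
    _write_tsv(prof.to_dataframe(), os.path.join(cfg.outdir, "rate_profile.tsv"), cfg)
    out = {"rate_profile_n_offsets": int(prof.offsets.size)}
    if cfg.track_path:
        cfg._require("track_path")
        tracks = read_bedgraph(cfg.track_path)
        pm = compute_matrix(peaks, tracks, flank=cfg.profile_flank, bin=cfg.bin)
        _write_tsv(pm.to_dataframe(),
                   os.path.join(cfg.outdir, "signal_profile.tsv"), cfg)
        mat = pd.DataFrame(pm.matrix, columns=[str(o) for o in pm.offsets])
        _write_tsv(mat, os.path.join(cfg.outdir, "signal_matrix.tsv"), cfg)
        out["signal_matrix_shape"] = list(pm.matrix.shape)
    return out


def run_maf_features_scores(cfg: RunConfig) -> dict:
    """Per-peak-set MAF averages, genomic-feature distributions and
    occupied-gene CRISPR-score averages."""
    if not cfg.peak_sets:
        raise ValidationError("config: at least one peaks.<label>=<path> entry needed")
    sets = {label: read_peaks(path, label=label)
            for label, path in sorted(cfg.peak_sets.items())}
    report: dict = {}
    if cfg.snp_path:
        cfg._require("snp_path")
        snps = load_snp_table(cfg.snp_path)
        report["maf"] = {}
        for label, ps in sets.items():
            r = mean_maf_over_peaks(ps, snps)
            report["maf"][label] = {"mean": r.mean, "sem": r.sem, "n_snps": r.n_snps}
    if cfg.genes_path:
        cfg._require("genes_path")
        model = load_gene_model(cfg.genes_path, cfg.blocks_path,
                                promoter_window=(cfg.promoter_upstream,
                                                 cfg.promoter_downstream))
        report["features"] = {label: feature_distribution(ps, model)
                              for label, ps in sets.items()}
        if cfg.scores_path:
            cfg._require("scores_path")
            scores = load_gene_scores(cfg.scores_path)
            report["crispr_scores"] = {}
            for label, ps in sets.items():
                genes = genes_occupied(ps, model)
                mean, sem, n = mean_gene_score(genes, scores)
                report["crispr_scores"][label] = {
                    "mean": mean, "sem": sem, "n_scored": n,
                    "n_occupied": len(genes)}
    if not report:
        raise ValidationError("config: nothing to do (need snp_path or genes_path)")
    os.makedirs(cfg.outdir, exist_ok=True)
    _write_json(report, os.path.join(cfg.outdir, "maf_features_scores.json"), cfg)
    return report


# ---------------------------------------------------------------------------
# synthetic dataset on disk
# ---------------------------------------------------------------------------

def simulate_dataset(outdir: str, seed: int = 0, *, n_peaks: int = 500,
                     n_g4: int = 600, linked_fraction: float = 0.6) -> RunConfig:
    """Write a complete toy dataset plus a ready-to-run config file.

    Emits genetic map, cold-preferring protein peaks (narrowPeak), a linked
    G4-like peak set, SNP table, signal track with a planted central dip,
    gene model + CRISPR-like scores, G4 test sequences and the truth record.
    Returns the :class:`RunConfig` pointing at the files.
    """
    os.makedirs(outdir, exist_ok=True)
    maps, land_truth = synthdata.make_genetic_map(synthdata.LandscapeSpec(seed=seed))
    lengths = land_truth["chromosome_lengths"]
    yy1, peaks_truth = synthdata.make_peaks(
        synthdata.PeakPlacementSpec(n_peaks=n_peaks, seed=seed),
        land_truth, label="protein")
    g4, g4_truth = synthdata.make_linked_peaks(
        yy1, land_truth, n_g4, linked_fraction, seed=seed, label="g4")
    snps, snp_truth = synthdata.make_snps(
        2e-3,
        {"coldspot": (0.04, 0.02), "hotspot": (0.12, 0.05),
         "background": (0.08, 0.04)},
        land_truth, seed=seed)
    tracks, track_truth = synthdata.make_tracks(yy1, lengths, seed=seed)
    model, scores, gene_truth = synthdata.make_gene_model_and_scores(
        100, lengths, seed=seed)
    g4_records, g4seq_truth = synthdata.make_g4_sequences([12, 8, 6, 0], seed=seed)

    paths = {k: os.path.join(outdir, v) for k, v in {
        "map": "genetic_map.tsv", "yy1": "protein_peaks.narrowPeak",
        "g4": "g4_peaks.bed", "snps": "snps.tsv", "track": "signal.bedgraph",
        "genes": "genes.tsv", "blocks": "gene_blocks.tsv",
        "scores": "crispr_scores.tsv", "fasta": "g4_sites.fasta",
    }.items()}
    write_genetic_map(maps, paths["map"])
    write_peaks(yy1, paths["yy1"], format="narrowPeak")
    write_peaks(g4, paths["g4"], format="bed3")
    write_snp_table(snps, paths["snps"])
    write_bedgraph(tracks, paths["track"])
    write_gene_model(model, paths["genes"], paths["blocks"])
    write_gene_scores(scores, paths["scores"])
    synthdata.write_fasta(g4_records, paths["fasta"])
    truth = {"landscape": land_truth, "peaks": peaks_truth, "g4_peaks": g4_truth,
             "snps": snp_truth, "tracks": track_truth, "genes": gene_truth,
             "g4_sequences": g4seq_truth}
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")

    cfg = RunConfig(
        map_path=paths["map"],
        peak_sets={"protein": paths["yy1"], "g4": paths["g4"]},
        g4_peaks_path=paths["g4"], yy1_peaks_path=paths["yy1"],
        snp_path=paths["snps"], track_path=paths["track"],
        genes_path=paths["genes"], blocks_path=paths["blocks"],
        scores_path=paths["scores"], fasta_path=paths["fasta"],
        seed=seed, outdir=os.path.join(outdir, "results"),
    )
    with open(os.path.join(outdir, "run.config"), "w") as fh:
        fh.write(cfg.to_text())
    return cfg
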