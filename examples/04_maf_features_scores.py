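"""Minor allele frequency over intervals, feature annotation, gene scores.

Cold regions accumulate less common variation (lower MAF); promoter-bound
factors occupy essential genes (lower CRISPR score).  Both contrasts are
planted and recovered here.
"""

from g4recomb import (Peak, PeakSet, feature_distribution, genes_occupied,
                      mean_gene_score, mean_maf_over_peaks)
from g4recomb import synthdata as sd

maps, truth = sd.make_genetic_map(sd.LandscapeSpec(seed=1))
snps, struth = sd.make_snps(
    2e-3, {"coldspot": (0.04, 0.02), "hotspot": (0.12, 0.05),
           "background": (0.08, 0.04)}, truth, seed=1)

for cls in ("coldspot", "hotspot"):
    regions = PeakSet(cls, [Peak(r["chrom"], r["start"], r["end"])
                            for r in truth["regions"] if r["class"] == cls])
    res = mean_maf_over_peaks(regions, snps)
    planted = struth["classes"][cls]["truncated_mean"]
    print(f"{cls:9s} mean MAF {res.mean:.4f} +/- {res.sem:.4f} "
          f"(planted {planted:.4f}, n={res.n_snps} SNPs)")

lengths = truth["chromosome_lengths"]
model, scores, gtruth = sd.make_gene_model_and_scores(100, lengths, seed=1)
mixture = {"promoter": 0.3, "utr5": 0.1, "cds": 0.1, "intron": 0.2,
           "utr3": 0.05, "intergenic": 0.25}
peaks, _ = sd.make_feature_peaks(model, lengths, mixture, 400, seed=1)
dist = feature_distribution(peaks, model)
print("feature distribution:",
      {k: round(v, 3) for k, v in dist.items() if v > 0})

occupied = genes_occupied(peaks, model)
mean, sem, n = mean_gene_score(occupied, scores)
print(f"occupied genes: {len(occupied)}; mean CRISPR score "
      f"{mean:.2f} +/- {sem:.2f} (n={n})")

# Coldspot SNPs show roughly a third the MAF of hotspot SNPs, the annotated
# feature shares match the planted mixture, and occupied genes average the
# blend of essential (-2.5) and neutral (0) score classes they were drawn from.
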