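# g4recomb

**Recombination-landscape annotation of protein-binding and G-quadruplex peak
sets.**

Homologous recombination (HR) is unevenly distributed across the human genome:
PRDM9-marked hotspots concentrate crossovers, while broad cold domains are
largely spared.  Guanine-quadruplex (G4) structures and the proteins that bind
them (e.g. the transcription factor YY1) are implicated in *suppressing* HR at
specific loci.  Testing such hypotheses computationally reduces to a recurring
set of interval statistics that relate ChIP-seq/CUT&Tag peak sets to a
population genetic map, to SNP variation, to chromatin signal, and to gene
annotation.  `g4recomb` implements that toolkit as a tested Python library for
genomicists analysing peak sets against the recombination landscape, with a
synthetic-data generator so every statistic is verifiable without downloading
multi-GB accessions.

## What it computes

Given a genetic map — per-chromosome anchors *(pos, rate, cM)* where the rate
ρᵢ (cM/Mb) applies on [posᵢ, posᵢ₊₁) and the cumulative genetic position
interpolates linearly,

&nbsp;&nbsp;&nbsp;&nbsp;cM(x) = cMᵢ + ρᵢ·(x − posᵢ)/10⁶,

the library provides:

* **Mean center rate** — mean ± SEM of ρ(center) over a peak set: the
  screening statistic ranking binding proteins by how recombination-cold
  their sites are.
* **Rate metaplots** — mean ρ(center + o) for offsets o ∈ ±5 kb at 50 bp
  steps.
* **Flanking genetic distance** — cM(center+F) − cM(center−F) per peak
  (F = 10 kb), compared against a seeded random-region null matched in
  chromosome composition and length (two-sided Student's *t*).
* **Overlap** with `bedtools intersect -wa` semantics (half-open, touching ≠
  overlapping), and stratification by relative enrichment
  (signalValue / max, threshold 0.2).
* **Fraction below average** — share of peaks with ρ(center) strictly below
  the physical-length-weighted genome-average rate.
* **Interval-averaged MAF** — mean minor allele frequency of SNP records
  inside peaks (each position once).
* **Signal matrices** — computeMatrix-style 50 bp binned aggregation of
  bedGraph tracks around peak centers.
* **Feature annotation** — peak-center assignment to promoter / 5′UTR / 3′UTR
  / CDS / intron / intergenic with a priority rule, plus occupied-gene CRISPR
  score averaging (lower = more essential).
* **G4Hunter** — per-base G/C-run scores in [−4, 4], sliding-window means
  (window 25, threshold 1.2), merged above-threshold windows as predicted
  G4s, and the per-region frequency.

All coordinates are 0-based half-open internally; 1-based sources (genetic
maps, VCF) are shifted on load, and `chr` prefixes are normalized away.

## Worked example

`examples/02_coldspot_analysis.py` simulates a 10 Mb landscape (background
1.2 cM/Mb, 30 hotspots at 10×, 20 coldspots at 0.1× covering ~10% of the
genome) and a 500-peak set that places 80% of its centers in coldspots:

```
genome average rate: 1.157 cM/Mb
peak centers:   0.366 +/- 0.038 cM/Mb (n=500)
random regions: 1.144 +/- 0.041 cM/Mb (n=500)
flanking cM (peaks vs random): 0.0087 vs 0.0226, t=-25.2, p=5.8e-109
fraction of peaks below the genome-average rate: 81.2%
```

The random-region null reproduces the genome average; the cold-preferring
peaks sit at a third of it, their ±10 kb windows accumulate less than half the
genetic distance, and >80% of them lie in below-average territory — the
signature of a recombination-cold binding landscape.  The other example
scripts demonstrate the map primitives, the signal-dip metaplot, MAF /
feature / score recovery, and G4Hunter scanning (planted frequencies
12 / 8 / 6 vs 0 recovered exactly).

A thin CLI mirrors the library: `g4recomb simulate`, `annotate-rate`,
`coldspot-report`, `profile`, `distance`, `maf`, `features`, `scores`,
`g4scan`, driven by a flat `key=value` config; outputs embed the seed and a
config hash and are byte-reproducible.

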