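# Methods

## The genetic-map model

A genetic map is stored per chromosome as anchors *(posᵢ, ρᵢ, cMᵢ)* with
strictly increasing positions, finite non-negative rates ρ (cM/Mb) and
non-decreasing cumulative genetic positions cM.  The rate is piecewise
constant on half-open intervals: ρᵢ applies on [posᵢ, posᵢ₊₁), and the last
anchor carries no forward interval.  Cumulative cM interpolates linearly
inside each interval, so distance queries are exact integrals of the step
function.  At load time the identity cMᵢ₊₁ = cMᵢ + ρᵢ·(posᵢ₊₁ − posᵢ)/10⁶ is
checked to 10⁻⁶ cM; violations warn rather than fail, because real map
releases carry rounded cumulative columns.

Conventions that matter and are therefore fixed package-wide:

* **Coordinates** are 0-based half-open internally.  Genetic-map files and
  VCF are 1-based and shifted on load; BED is native.  Whether upstream map
  sources count from 0 or 1 is not always documented; a single internal
  convention prevents off-by-one drift between statistics.
* **Chromosome names**: `chr1` and `1` are unified by stripping the
  configurable `chr` prefix — the ENCODE vs 1000 Genomes naming mismatch is
  the most common silent failure in this class of analysis.
* **Outside-map policy**: rate queries outside [first, last) return 0.0 with
  a flag; cumulative-cM queries clamp to the terminal anchor and flag.
  Averaging statistics *exclude* flagged peaks rather than imputing 0 —
  imputation would bias every result toward "cold" — and report the exclusion
  count.

The genome-average rate is total genetic length over total physical length,
Σ(cM_last − cM_first) / Σ(pos_last − pos_first) × 10⁶, i.e. the per-bp mean
rate over the mapped span; single-anchor maps are skipped.

## Peak statistics

Peak centers are ⌊(start+end)/2⌋.  The mean center rate, its ±5 kb / 50 bp
rate profile, and the flanking genetic distance cM(c+F) − cM(c−F) (default
F = 10 kb, center-anchored; edge-anchored available) are all reported as
mean ± SEM with sample-variance SEM (n − 1).  Group comparisons use the
two-sided two-sample Student's *t*-test with pooled variance (Welch behind a
flag); the degenerate equal-constant case is defined as t = 0, p = 1.  The
10 kb window may be anchored at peak centers or peak edges; center anchoring
is the default because every other statistic here is center-referenced.

The random-region null draws, per peak: a chromosome from the template's
per-chromosome proportions, a length resampled from the template (or a fixed
200 bp), and an independent uniform start within the mapped bounds.  No
overlap-avoidance is applied — the null models independent placement, and
collisions are reported as duplicate warnings.  Draws are bit-reproducible
for a given seed.

Overlap follows `bedtools -wa`: every `a` peak overlapping ≥ 1 bp of `b`,
once per pair without deduplication or once per peak with it (the default for
statistics).  Touching half-open intervals do not overlap.  Relative
enrichment is signalValue divided by the set maximum, so the 0.2 threshold
lives on (0, 1]; ties go to the high stratum.

## MAF aggregation

"Average MAF of a peak set" means the mean over dbSNP-record positions inside
peaks: non-variant bases contribute nothing, and a SNP under two overlapping
peaks counts once (intervals are unioned first).  The alternative reading —
every covered base as an observation with non-SNP bases at 0 — changes the
scale by roughly the SNP density and is implemented as `mode="all_bases"` for
sensitivity analysis only.  Frequencies are folded to the minor allele,
min(f, 1 − f); duplicate positions collapse keeping the larger MAF.

## Signal matrices

`compute_matrix` cuts [center − 5 kb, center + 5 kb) into 50 bp bins; a bin's
value is the coverage-weighted mean of the bedGraph step function over the
bin, with uncovered bases scoring 0 by default (the deepTools
missing-data-as-zero behaviour; skip-missing is available).  The aggregate is
the mean of per-peak bin means — not the pooled per-bp mean — matching the
common metaplot convention.  Peaks are unstranded; no orientation flipping is
applied.  Integrals are evaluated from a precomputed piecewise-linear
antiderivative, so results are exact for step tracks.

## Feature annotation and gene scores

A peak's feature is decided by its **center** (any-overlap conventions shift
the percentages), resolved by the priority promoter > 5′UTR > 3′UTR > CDS >
intron > intergenic when annotations overlap.  The promoter is a derived
window around the TSS, (2000 up, 500 down) by default — a common annotation
default, configurable because published pie charts rarely state theirs.
Exonic sequence is split into 5′UTR / CDS / 3′UTR.  A gene is "occupied" if
its body ∪ promoter window overlaps ≥ 1 peak; occupied-gene sets are averaged
over a CRISPR-score table (average log₂ fold change of sgRNAs targeting the
gene; lower = more essential), skipping unscored genes with a count.

## G4Hunter

Each base scores +min(k, 4) in a run of k consecutive G, −min(k, 4) in a run
of k C, 0 for A/T/N.  A window (default 25 bp) slides by 1; windows with
|mean| ≥ 1.2 are hits, and hits of one sign that overlap or abut merge into a
single predicted G4.  "Frequency" is the merged count per region; both signs
are scanned, the sign giving the strand.  The window count (pre-merge) is
also exposed: it is monotone non-increasing in the threshold, whereas the
merged count can transiently rise when a higher threshold splits a bridged
region — a subtlety worth knowing when comparing settings.  Defaults are the
published tool's canonical settings and are recorded in output metadata.

## The synthetic generator: what it emulates, what it does not

The generator's defaults define the study conditions used throughout the
tests:

* **Landscape**: 10 Mb over two 5 Mb chromosomes; background 1.2 cM/Mb
  (about the human genome-wide average); 30 hotspots of 2 kb at 10×
  background (narrow PRDM9-like peaks); 20 coldspots of 50 kb at 0.1×,
  together ~10% of the genome (broad low-recombination domains).  Regions are
  placed without overlap by rejection sampling; the truth record carries every
  region and the exact genome-average rate.
* **Peaks**: n = 500, lengths ~N(300, 100²) clipped at 50 bp, lognormal
  enrichments; `cold_preference` p = 0.8 is the probability a center is drawn
  from coldspot bp rather than uniformly, so the expected coldspot fraction is
  p + (1 − p)·(coldspot bp share).  A linked-peak generator centers a second
  set near an existing one with given probability, creating overlapping
  datasets.
* **SNPs**: Poisson-placed at 2×10⁻³ per bp with truncated-normal MAFs per
  landscape class — cold μ = 0.04, hot μ = 0.12, background μ = 0.08,
  truncated to [0.01, 0.5].  Truncation shifts the means; the truth record
  stores the exact truncated-normal expectations the recovery tests compare
  against.  This is deliberately *not* a realistic site-frequency spectrum:
  recovery tests need known means, not realism.
* **Tracks**: whole-chromosome 50 bp steps at baseline 1.0 with a rectangular
  dip (depth 0.5, width 500 bp) at each peak center and i.i.d. Gaussian step
  noise (σ = 0.2).
* **Genes**: non-overlapping genes with an 800 bp 5′UTR, three 500 bp CDS
  exons, 2 kb introns and a 300 bp 3′UTR; the long 5′UTR keeps 5′UTR
  territory non-empty under the default promoter window.  Scores are normal
  per essentiality class (essential μ = −2.5, neutral μ = 0, σ = 0.5,
  essential fraction 0.3).  Feature-mixture peaks are planted in the
  *priority-resolved* territory of each class, so recovered distributions are
  exact multinomial draws.
* **G4 sequences**: A/T background with planted `(GGGTTA)₃GGG` motifs
  (window-25 mean 1.44) separated by more than a window, so each motif yields
  exactly one merged prediction.

One global seed fans out to independent per-generator streams
(`SeedSequence([stream_tag, seed])`), so adding a generator never perturbs
another's draws.  What passing these tests does *not* show: robustness to
real-data features the generator omits — mappability artifacts, blacklist
regions, GC-coupled SNP density, overlapping transcript isoforms, sex-specific
maps, and rate uncertainty in the map itself.

## Numerical choices and problem sizes

Map-engine agreement with brute-force per-bp integration is asserted to
10⁻⁹ cM; map self-consistency warns at 10⁻⁶ cM.  Monte-Carlo recovery checks
use 3·SEM bands; categorical recoveries use binomial/multinomial 99%
intervals (pooled across seeds where several seeds are run, since per-seed
99% bands over 20 seeds would fail spuriously by construction).  Test and
acceptance problem sizes — 200 random maps, 500 overlap instances, 500 peaks
× 20 seeds, 200 type-I replicates, 300-peak metaplots — keep the full suite
under a minute of compute while leaving standard errors small against the
planted effects.  Statistical edge cases are defined explicitly: SEM of a
single observation is NaN; zero pooled variance with equal means gives
p = 1.0, with unequal means p = 0.0.

## Known limitations

Real-data percentages (feature pies, genome-wide MAF levels) depend on the
annotation release and SNP set used; the package reproduces conventions, not
those external inputs.  bigWig input is out of scope (bedGraph only), as are
peak calling, LD-based map estimation, GO enrichment and isoform-aware
annotation.  The pooled-variance t-test mirrors common practice for these
comparisons but is not robust to strong variance heterogeneity; Welch's
variant is one flag away.
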