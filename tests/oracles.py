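"""Independent brute-force oracles the fast implementations are checked against.

Each oracle takes the slow, obviously-correct route: per-bp integration for
genetic distances, all-pairs scanning for interval overlap, full window
enumeration for sequence scans.  They deliberately share no code path with the
implementations under test.
"""

from __future__ import annotations

import numpy as np


def bp_integral_cm(positions, rates, a: int, b: int) -> float:
    """Genetic distance over [a, b) by summing the per-bp rate.

    The rate of base p is that of the anchor interval containing it
    (piecewise-constant, half-open); bases outside the mapped span contribute
    nothing, matching clamping to the terminal anchors.
    """
    positions = np.asarray(positions)
    rates = np.asarray(rates)
    bps = np.arange(max(a, positions[0]), min(b, positions[-1]), dtype=np.int64)
    if bps.size == 0:
        return 0.0
    idx = np.searchsorted(positions, bps, side="right") - 1
    return float(rates[idx].sum() / 1e6)


def bp_mean_rate(positions, rates) -> float:
    """Per-bp mean of the piecewise rate over the mapped span."""
    widths = np.diff(np.asarray(positions))
    return float((np.asarray(rates)[:-1] * widths).sum() / widths.sum())


def brute_overlap(a_ivs, b_ivs) -> list[tuple[int, int]]:
    """All (i, j) index pairs with a_ivs[i] overlapping b_ivs[j] >= 1 bp
    (half-open intervals, same chromosome assumed)."""
    out = []
    for i, (s1, e1) in enumerate(a_ivs):
        for j, (s2, e2) in enumerate(b_ivs):
            if s1 < e2 and s2 < e1:
                out.append((i, j))
    return out


def brute_g4_hits(base_scores, window: int, threshold: float) -> dict[str, int]:
    """Count merged above-threshold regions per strand by painting a per-bp
    mask from every enumerated window and counting connected runs."""
    scores = np.asarray(base_scores, dtype=float)
    n = scores.size
    counts = {}
    for sign, strand in ((1, "+"), (-1, "-")):
        mask = np.zeros(n, dtype=bool)
        hit_any = False
        prev_end = None
        runs = 0
        for i in range(n - window + 1):
            if sign * scores[i:i + window].mean() >= threshold:
                mask[i:i + window] = True
        # merged hits abut when consecutive hit windows are <= window apart,
        # which is exactly connectivity of the painted mask
        in_run = False
        for v in mask:
            if v and not in_run:
                runs += 1
                in_run = True
            elif not v:
                in_run = False
        counts[strand] = runs
    return counts


def brute_bin_means(starts, ends, values, edges, *, missing_as_zero=True):
    """Per-bin coverage-weighted means by expanding the track to per-bp values."""
    lo, hi = int(edges[0]), int(edges[-1])
    per_bp = np.zeros(hi - lo)
    covered = np.zeros(hi - lo, dtype=bool)
    for s, e, v in zip(starts, ends, values):
        s2, e2 = max(int(s), lo), min(int(e), hi)
        if s2 < e2:
            per_bp[s2 - lo:e2 - lo] = v
            covered[s2 - lo:e2 - lo] = True
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        seg = per_bp[int(a) - lo:int(b) - lo]
        cov = covered[int(a) - lo:int(b) - lo]
        if missing_as_zero:
            out.append(seg.sum() / (int(b) - int(a)))
        else:
            out.append(seg[cov].mean() if cov.any() else np.nan)
    return np.array(out)


def brute_snps_in_peaks(peak_ivs, snp_positions, snp_mafs):
    """MAFs of SNPs inside any peak, each (chrom, pos) once — all on one
    chromosome; the caller loops chromosomes."""
    picked = {}
    for s, e in peak_ivs:
        for p, m in zip(snp_positions, snp_mafs):
            if s <= p < e:
                picked[p] = m
    return np.array([picked[p] for p in sorted(picked)])
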