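"""G4Hunter scoring: sequence-based prediction of G-quadruplex-forming regions.

Each base receives an integer score from the length of the G- or C-run it sits
in: a base inside a run of k consecutive G scores +min(k, 4), inside a run of
k C scores -min(k, 4); A/T/N score 0.  A window (default 25 bp) slides one
base at a time; windows whose mean |score| reaches the threshold (default 1.2)
are hits, positive sign marking a G4 on the given strand, negative on the
reverse complement.  Overlapping or abutting hit windows of the same sign
merge into one predicted G4, and the "frequency" of a region is the number of
merged predictions — the region-level summary used to contrast candidate G4
sites against control sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["G4Hit", "G4Scan", "g4hunter_base_scores", "g4hunter_scan", "scan_fasta"]

DEFAULT_WINDOW = 25
DEFAULT_THRESHOLD = 1.2


@dataclass(frozen=True)
class G4Hit:
    """One merged predicted G4: half-open interval, strand and extreme window mean."""

    start: int
    end: int
    strand: str          # '+' for G-runs, '-' for C-runs
    max_score: float     # window mean with the largest magnitude inside the hit


@dataclass
class G4Scan:
    sequence_id: str
    base_scores: np.ndarray
    window: int
    threshold: float
    hits: list[G4Hit]

    @property
    def frequency(self) -> int:
        return len(self.hits)

    @property
    def n_hit_windows(self) -> int:
        """Number of above-threshold windows (both strands) before merging.

        Unlike ``frequency``, this count is monotone non-increasing in the
        threshold; merged-region counts can transiently rise when a higher
        threshold splits one bridged region into two.
        """
        cs = np.concatenate(([0], np.cumsum(self.base_scores, dtype=np.int64)))
        means = (cs[self.window:] - cs[:-self.window]) / self.window
        return int((np.abs(means) >= self.threshold).sum())


def g4hunter_base_scores(seq: str) -> np.ndarray:
    """Per-base run scores in [-4, 4]; case-insensitive, N scores 0."""
    s = seq.upper()
    n = len(s)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"invalid base {s[pos]!r} at position {pos}")
    scores = np.zeros(n, dtype=np.int8)
    if n == 0:
        return scores
    # run-length encode
    boundaries = np.flatnonzero(np.concatenate(([True], arr[1:] != arr[:-1], [True])))
    for i in range(boundaries.size - 1):
        a, b = boundaries[i], boundaries[i + 1]
        base = arr[a]
        if base == ord("G"):
            scores[a:b] = min(b - a, 4)
        elif base == ord("C"):
            scores[a:b] = -min(b - a, 4)
    return scores


def g4hunter_scan(
    seq: str,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    sequence_id: str = "seq",
) -> G4Scan:
    """Slide a window over the base scores and merge above-threshold windows
    into predicted G4s (both signs scanned; sign gives the strand)."""
    if len(seq) < window:
        raise ValidationError(
            f"{sequence_id}: sequence length {len(seq)} < window {window}"
        )
    scores = g4hunter_base_scores(seq)
    cs = np.concatenate(([0], np.cumsum(scores, dtype=np.int64)))
    means = (cs[window:] - cs[:-window]) / window  # mean of window starting at i
    hits: list[G4Hit] = []
    for sign, strand in ((1, "+"), (-1, "-")):
        signed = sign * means
        above = np.flatnonzero(signed >= threshold)
        if above.size == 0:
            continue
        # merge hit windows [i, i+window) that overlap or abut
        breaks = np.flatnonzero(np.diff(above) > window)
        groups = np.split(above, breaks + 1)
        for grp in groups:
            start, end = int(grp[0]), int(grp[-1]) + window
            extreme = float(sign * signed[grp].max())
            hits.append(G4Hit(start=start, end=end, strand=strand, max_score=extreme))
    hits.sort(key=lambda h: (h.start, h.end))
    return G4Scan(sequence_id=sequence_id, base_scores=scores, window=window,
                  threshold=threshold, hits=hits)


def scan_fasta(
    path, window: int = DEFAULT_WINDOW, threshold: float = DEFAULT_THRESHOLD
) -> list[G4Scan]:
    """Scan every record of a FASTA file."""
    from Bio import SeqIO

    return [
        g4hunter_scan(str(rec.seq), window=window, threshold=threshold,
                      sequence_id=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
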