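"""Small shared helpers: chromosome-name normalization and mean/SEM summaries."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["normalize_chromosome", "mean_sem"]


def normalize_chromosome(name: str, strip_prefix: str = "chr") -> str:
    """Unify chromosome labels across naming conventions.

    ENCODE-style files say ``chr1`` where 1000 Genomes / dbSNP tables say ``1``;
    mixing the two silently empties every join, so all loaders funnel labels
    through this rule.  Stripping is configurable; pass ``strip_prefix=""`` to
    keep labels verbatim.
    """
    name = str(name).strip()
    if strip_prefix and name.startswith(strip_prefix):
        return name[len(strip_prefix):]
    return name


def mean_sem(values) -> tuple[float, float, int]:
    """Return (mean, SEM, n) of a 1-D collection.

    SEM uses the sample standard deviation (n - 1 denominator). For n == 1 the
    SEM is NaN; for n == 0 a ValueError is raised (callers turn this into a
    domain-specific validation error with context).
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("mean_sem: empty input")
    mean = float(arr.mean())
    if n < 2:
        return mean, math.nan, n
    sem = float(arr.std(ddof=1) / math.sqrt(n))
    return mean, sem, n
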