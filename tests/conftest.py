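import numpy as np
import pytest

from g4recomb import GeneticMap, Peak, PeakSet
from g4recomb import synthdata as sd


@pytest.fixture
def toy_map() -> GeneticMap:
    """Three anchors: rate 1.0 on [100, 1100), 3.0 on [1100, 2100)."""
    return GeneticMap(
        chromosome="1",
        positions=np.array([100, 1100, 2100]),
        rates=np.array([1.0, 3.0, 0.0]),
        cum_cm=np.array([0.0, 0.001, 0.004]),
    )


@pytest.fixture
def uniform_map() -> GeneticMap:
    """Constant 2.0 cM/Mb over [0, 1_000_000)."""
    return GeneticMap(
        chromosome="1",
        positions=np.array([0, 1_000_000]),
        rates=np.array([2.0, 0.0]),
        cum_cm=np.array([0.0, 2.0]),
    )


@pytest.fixture(scope="session")
def landscape():
    """Default 10 Mb two-chromosome landscape with planted hot/cold spots."""
    return sd.make_genetic_map(sd.LandscapeSpec(seed=0))


@pytest.fixture(scope="session")
def gene_world():
    """Gene model + scores on the default chromosome lengths."""
    lengths = {"1": 5_000_000, "2": 5_000_000}
    model, scores, truth = sd.make_gene_model_and_scores(100, lengths, seed=0)
    return model, scores, truth, lengths


def random_interval_set(rng: np.random.Generator, n: int, span: int = 10_000):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, 200, size=n)
    return [(int(s), int(s + l)) for s, l in zip(starts, lengths)]


def peakset_from_intervals(ivs, chrom="1", label="t") -> PeakSet:
    return PeakSet(label, [Peak(chrom, s, e) for s, e in ivs])
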