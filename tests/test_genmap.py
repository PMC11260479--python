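import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from g4recomb import (GeneticMap, ParseError, ValidationError, cm_at,
                      genetic_distance, genome_average_rate, load_genetic_map,
                      rate_at, write_genetic_map)

from oracles import bp_integral_cm, bp_mean_rate

TOY_TEXT = (
    "chromosome position rate map\n"
    "1 101 1.0 0.0\n"
    "1 1101 3.0 0.001\n"
    "1 2101 0.0 0.004\n"
)


class TestLoad:
    def test_toy_file_roundtrip(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text(TOY_TEXT)
        maps = load_genetic_map(p)
        m = maps["1"]
        assert m.positions.tolist() == [100, 1100, 2100]  # shifted to 0-based
        assert m.rates.tolist() == [1.0, 3.0, 0.0]
        assert m._consistent
        # round trip through the writer
        out = tmp_path / "out.tsv"
        write_genetic_map(maps, out)
        again = load_genetic_map(out)["1"]
        assert np.array_equal(again.positions, m.positions)
        assert np.allclose(again.cum_cm, m.cum_cm)

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(ParseError):
            load_genetic_map(p)
        p.write_text("chromosome position rate map\n")
        with pytest.raises(ParseError):
            load_genetic_map(p)

    def test_two_chromosomes_partition(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("c p r m\n2 501 1.0 0.0\n1 101 2.0 0.0\n"
                     "1 1101 0.0 0.002\n2 1501 0.0 0.001\n")
        maps = load_genetic_map(p)
        assert set(maps) == {"1", "2"}
        assert maps["1"].positions.tolist() == [100, 1100]
        assert maps["2"].positions.tolist() == [500, 1500]

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("c p r m\n1 101 1.0 0.0\n1 oops 3.0 0.001\n")
        with pytest.raises(ParseError, match="line 3"):
            load_genetic_map(p)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError, match="finite and >= 0"):
            GeneticMap("1", [0, 100], [-1.0, 0.0], [0.0, 0.0])

    def test_decreasing_positions_rejected(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            GeneticMap("1", [100, 50], [1.0, 0.0], [0.0, 0.1])

    def test_inconsistent_cum_cm_warns_not_fails(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            m = GeneticMap("1", [0, 1_000_000], [1.0, 0.0], [0.0, 9.0])
        assert not m._consistent

    def test_chromosome_filter_and_chr_prefix(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("c p r m\nchr1 101 1.0 0.0\nchr2 101 1.0 0.0\n")
        maps = load_genetic_map(p, chromosome_filter={"1"})
        assert set(maps) == {"1"}


class TestRateAt:
    def test_inside_first_interval(self, toy_map):
        assert rate_at(toy_map, 600) == 1.0

    def test_anchor_boundary_is_left_closed(self, toy_map):
        assert rate_at(toy_map, 1100) == 3.0

    def test_outside_map_policy(self, toy_map):
        vals, in_map = toy_map.rate_at_many([50, 2100, 5000, 600])
        assert vals.tolist() == [0.0, 0.0, 0.0, 1.0]
        assert in_map.tolist() == [False, False, False, True]

    def test_piecewise_constant_within_interval(self, toy_map):
        rng = np.random.default_rng(0)
        pos = rng.integers(1100, 2100, size=200)
        vals, in_map = toy_map.rate_at_many(pos)
        assert in_map.all()
        assert np.unique(vals).tolist() == [3.0]


class TestCmAt:
    def test_anchor_identity(self, toy_map):
        assert cm_at(toy_map, 1100) == pytest.approx(0.001, abs=1e-12)

    def test_interpolation(self, toy_map):
        # 1.0 cM/Mb over 500 bp
        assert cm_at(toy_map, 600) == pytest.approx(0.0005, abs=1e-12)

    def test_clamping_flags(self, toy_map):
        cm, clamped = toy_map.cm_at_many([0, 2100, 9999])
        assert cm.tolist() == [0.0, 0.004, 0.004]
        assert clamped.tolist() == [True, False, True]

    def test_additivity(self, toy_map):
        a, b, c = 150, 900, 2050
        lhs = cm_at(toy_map, c) - cm_at(toy_map, a)
        rhs = (cm_at(toy_map, b) - cm_at(toy_map, a)) + (cm_at(toy_map, c) - cm_at(toy_map, b))
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestGeneticDistance:
    def test_spans_first_interval(self, toy_map):
        assert genetic_distance(toy_map, 100, 1100) == pytest.approx(0.001, abs=1e-12)

    def test_zero_width(self, toy_map):
        assert genetic_distance(toy_map, 600, 600) == 0.0

    def test_across_anchor(self, toy_map):
        # frozen from the per-bp integration oracle: 500 bp at 1.0 + 500 bp at 3.0
        expected = bp_integral_cm(toy_map.positions, toy_map.rates, 600, 1600)
        assert expected == pytest.approx(0.002, abs=1e-12)
        assert genetic_distance(toy_map, 600, 1600) == pytest.approx(expected, abs=1e-9)

    def test_inverted_arguments_rejected(self, toy_map):
        with pytest.raises(ValueError):
            genetic_distance(toy_map, 1600, 600)


class TestGenomeAverageRate:
    def test_toy_definition(self, toy_map):
        assert genome_average_rate({"1": toy_map}) == pytest.approx(2.0)

    def test_uniform_rate_identity(self, uniform_map):
        assert genome_average_rate({"1": uniform_map}) == pytest.approx(2.0)

    def test_two_chromosomes_weighted(self, toy_map, uniform_map):
        maps = {"1": toy_map, "2": uniform_map}
        expected = ((0.004 + 2.0) / (2000 + 1_000_000)) * 1e6
        got = genome_average_rate(maps)
        assert got == pytest.approx(expected)
        # equals the per-bp brute-force mean over the union of spans
        brute = (bp_mean_rate(toy_map.positions, toy_map.rates) * 2000
                 + bp_mean_rate(uniform_map.positions, uniform_map.rates) * 1_000_000
                 ) / 1_002_000
        assert got == pytest.approx(brute, abs=1e-9)

    def test_all_degenerate_rejected(self):
        m = GeneticMap("1", [100], [0.0], [0.0])
        with pytest.raises(ValidationError):
            genome_average_rate({"1": m})


@st.composite
def random_maps(draw):
    n = draw(st.integers(min_value=2, max_value=20))
    gaps = draw(st.lists(st.integers(min_value=1, max_value=500),
                         min_size=n - 1, max_size=n - 1))
    start = draw(st.integers(min_value=0, max_value=1000))
    positions = np.concatenate([[start], start + np.cumsum(gaps)])
    rates = np.array(draw(st.lists(
        st.floats(min_value=0.0, max_value=50.0, allow_nan=False),
        min_size=n, max_size=n)))
    cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(positions) / 1e6)])
    return GeneticMap("1", positions, rates, cum)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(random_maps(), st.integers(min_value=0, max_value=1))
def test_cm_at_matches_per_bp_integration(gmap, _):
    """Linear cum-cM interpolation equals brute-force per-bp rate summation."""
    rng = np.random.default_rng(abs(hash((gmap.start, gmap.end))) % 2**31)
    queries = rng.integers(gmap.start, gmap.end + 1, size=(10, 2))
    for a, b in np.sort(queries, axis=1):
        oracle = bp_integral_cm(gmap.positions, gmap.rates, int(a), int(b))
        assert gmap.genetic_distance(int(a), int(b)) == pytest.approx(oracle, abs=1e-9)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(random_maps())
def test_cm_at_monotone_nondecreasing(gmap):
    pos = np.linspace(gmap.start, gmap.end, 50).astype(np.int64)
    cm, _ = gmap.cm_at_many(pos)
    assert np.all(np.diff(cm) >= -1e-12)
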