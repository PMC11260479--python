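import numpy as np
import pytest

from g4recomb import (Gene, GeneModel, GeneScoreTable, Peak, PeakSet,
                      ValidationError, assign_feature, feature_distribution,
                      feature_territory, genes_occupied, load_gene_model,
                      mean_gene_score, overlap_wa)
from g4recomb import synthdata as sd
from g4recomb.genefeatures import load_gene_scores, write_gene_model


def simple_gene(name="g1", start=10_000, strand="+"):
    """utr5 200 | cds 500 | intron 1000 | cds 500 | utr3 200 on + strand."""
    sizes = [("utr5", 200), ("cds", 500), ("intron", 1000), ("cds", 500),
             ("utr3", 200)]
    if strand == "-":
        sizes = sizes[::-1]
    blocks, cursor = [], start
    for feat, sz in sizes:
        blocks.append((feat, cursor, cursor + sz))
        cursor += sz
    tss, tes = (start, cursor - 1) if strand == "+" else (cursor - 1, start)
    return Gene(name=name, chromosome="1", strand=strand, tss=tss, tes=tes,
                blocks=blocks)


class TestAssignFeature:
    def test_promoter_upstream_plus_strand(self):
        model = GeneModel([simple_gene()], promoter_window=(2000, 500))
        peak = Peak("1", 9650, 9750)  # center 9700, 300 bp upstream of TSS
        assert assign_feature(peak, model) == "promoter"

    def test_promoter_wins_over_intron_of_other_gene(self):
        host = simple_gene("host", start=10_000)
        # TSS of 'other' sits inside host's intron: its promoter overlaps there
        other = Gene("other", "1", "+", tss=11_500, tes=11_800,
                     blocks=[("cds", 11_500, 11_801)])
        model = GeneModel([host, other])
        peak = Peak("1", 11_000, 11_100)  # center in host intron + other promoter
        assert assign_feature(peak, model) == "promoter"

    def test_far_from_genes_is_intergenic(self):
        model = GeneModel([simple_gene()])
        assert assign_feature(Peak("1", 1_000_000, 1_000_100), model) == "intergenic"

    def test_minus_strand_promoter_is_downstream_coordinates(self):
        g = simple_gene("m", start=50_000, strand="-")
        model = GeneModel([g], promoter_window=(2000, 500))
        # upstream of a minus-strand TSS means higher coordinates
        peak = Peak("1", g.tss + 900, g.tss + 1000)
        assert assign_feature(peak, model) == "promoter"

    def test_block_features_resolved(self):
        model = GeneModel([simple_gene()])
        center_of = {"utr5": 10_100, "cds": 10_600, "intron": 11_200,
                     "utr3": 12_300}
        for feat, c in center_of.items():
            got = assign_feature(Peak("1", c - 10, c + 10), model)
            expect = "promoter" if feat == "utr5" else feat  # window shadows utr5
            assert got == expect


class TestFeatureDistribution:
    def test_all_promoter(self):
        model = GeneModel([simple_gene()])
        peaks = PeakSet("p", [Peak("1", 9000, 9100) for _ in range(4)])
        dist = feature_distribution(peaks, model)
        assert dist["promoter"] == 1.0

    def test_sums_to_one(self, gene_world):
        model, _, _, lengths = gene_world
        peaks, _ = sd.make_feature_peaks(
            model, lengths, {"promoter": 0.3, "intron": 0.4, "intergenic": 0.3},
            120, seed=1)
        dist = feature_distribution(peaks, model)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            feature_distribution(PeakSet("p"), GeneModel([simple_gene()]))

    def test_mixture_recovery_multinomial(self, gene_world):
        """A PRDM9-like mixture (intron/intergenic-dominated) is recovered
        within multinomial 99% intervals."""
        model, _, _, lengths = gene_world
        mixture = {"promoter": 0.02, "utr5": 0.02, "utr3": 0.02, "cds": 0.043,
                   "intron": 0.424, "intergenic": 0.473}
        n = 1000
        peaks, truth = sd.make_feature_peaks(model, lengths, mixture, n, seed=2)
        dist = feature_distribution(peaks, model)
        for feat, p in mixture.items():
            ci = 2.576 * np.sqrt(p * (1 - p) / n)
            assert abs(dist[feat] - p) <= ci + 1e-12, feat
            # the generator's own truth agrees exactly with the annotation
            assert dist[feat] == pytest.approx(truth["realized"][feat], abs=1e-12)


class TestGenesOccupied:
    def test_peak_in_gene_body(self):
        model = GeneModel([simple_gene()])
        assert genes_occupied(PeakSet("p", [Peak("1", 10_400, 10_500)]), model) == {"g1"}

    def test_shared_promoter_of_divergent_genes(self):
        left = simple_gene("left", start=8_000, strand="-")   # ends ~10400, TSS at top
        right = simple_gene("right", start=11_000, strand="+")
        model = GeneModel([left, right], promoter_window=(2000, 500))
        # peak in the 600 bp between them: upstream of both TSSs
        occ = genes_occupied(PeakSet("p", [Peak("1", 10_500, 10_900)]), model)
        assert occ == {"left", "right"}

    def test_no_overlap_empty(self):
        model = GeneModel([simple_gene()])
        assert genes_occupied(PeakSet("p", [Peak("1", 500_000, 500_100)]), model) == set()

    def test_idempotent_under_self_overlap(self, gene_world):
        model, _, _, lengths = gene_world
        peaks, _ = sd.make_feature_peaks(
            model, lengths, {"cds": 0.5, "intergenic": 0.5}, 60, seed=3)
        assert genes_occupied(overlap_wa(peaks, peaks), model) == \
            genes_occupied(peaks, model)


class TestMeanGeneScore:
    def test_basic_mean(self):
        table = GeneScoreTable({"a": -1.0, "b": -3.0})
        mean, sem, n = mean_gene_score({"a", "b"}, table)
        assert mean == -2.0 and n == 2

    def test_unscored_genes_excluded(self):
        table = GeneScoreTable({"a": -1.0})
        mean, sem, n = mean_gene_score({"a", "zzz"}, table)
        assert n == 1 and mean == -1.0

    def test_no_scored_genes_rejected(self):
        with pytest.raises(ValidationError):
            mean_gene_score({"zzz"}, GeneScoreTable({"a": 0.0}))

    def test_essentiality_class_recovery(self, gene_world):
        """Class-pure gene sets recover the planted score means, preserving
        essential < neutral."""
        model, scores, truth, _ = gene_world
        ess = {g for g, e in truth["essential"].items() if e}
        neu = {g for g, e in truth["essential"].items() if not e}
        me, se, _ = mean_gene_score(ess, scores)
        mn, sn, _ = mean_gene_score(neu, scores)
        assert abs(me - truth["score_mean_essential"]) < 3 * se
        assert abs(mn - truth["score_mean_neutral"]) < 3 * sn
        assert me < mn


class TestTerritoryAndIO:
    def test_territory_partitions_chromosome(self, gene_world):
        model, _, _, lengths = gene_world
        terr = feature_territory(model, {"1": lengths["1"]})["1"]
        total = sum(e - s for ivs in terr.values() for s, e in ivs)
        assert total == lengths["1"]
        # disjointness: sorted starts never precede previous end
        allivs = sorted(iv for ivs in terr.values() for iv in ivs)
        assert all(a[1] <= b[0] for a, b in zip(allivs, allivs[1:]))

    def test_gene_tsv_roundtrip(self, tmp_path, gene_world):
        model, scores, _, _ = gene_world
        write_gene_model(model, tmp_path / "genes.tsv", tmp_path / "blocks.tsv")
        back = load_gene_model(tmp_path / "genes.tsv", tmp_path / "blocks.tsv")
        assert len(back.genes) == len(model.genes)
        g0, b0 = model.genes[0], back.genes[0]
        assert (g0.tss, g0.tes, g0.blocks) == (b0.tss, b0.tes, b0.blocks)

    def test_bed12_loader_derives_blocks(self, tmp_path):
        # 2 exons, thick (CDS) region [150, 420): exon1 = 100 utr5 + 50 cds,
        # exon2 = 120 cds + 80 utr3, intron between
        bed = tmp_path / "m.bed12"
        bed.write_text("chr1\t50\t500\tg\t0\t+\t150\t420\t0\t2\t150,200\t0,250\n")
        model = load_gene_model(bed)
        g = model.genes[0]
        assert g.tss == 50 and g.strand == "+"
        assert ("utr5", 50, 150) in g.blocks
        assert ("cds", 150, 200) in g.blocks
        assert ("intron", 200, 300) in g.blocks
        assert ("cds", 300, 420) in g.blocks
        assert ("utr3", 420, 500) in g.blocks

    def test_scores_tsv(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("gene\tscore\na\t-2.5\nb\t0.1\n")
        t = load_gene_scores(p)
        assert t.scores == {"a": -2.5, "b": 0.1}
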