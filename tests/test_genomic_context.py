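import numpy as np
import pandas as pd
import pytest
import scipy.stats

from lovis.genomic_context import (
    annotate_nearest_gene,
    bin_by_distance,
    chisq_yates,
    classify_activity,
    coverage_matrix,
    feature_pca,
    find_motif_positions,
    generate_random_is,
    peak_distance,
    proximity_enrichment,
)


def motif_free_genome(length, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    while "GTAC" in seq:
        i = seq.find("GTAC")
        seq = seq[: i + 1] + "A" + seq[i + 2 :]
    return seq


class TestRandomIs:
    def test_all_sites_near_single_motif(self):
        seq = motif_free_genome(20_000, seed=1)
        seq = seq[:5000] + "GTAC" + seq[5004:]
        sites = generate_random_is({"chr1": seq}, n=10, max_dist=1500, seed=3)
        pos0 = sites["pos"] - 1
        assert ((pos0 >= 3500) & (pos0 <= 6503)).all()

    def test_motif_free_genome_errors(self):
        with pytest.raises(ValueError, match="unsatisfiable"):
            generate_random_is({"chr1": motif_free_genome(5000)}, n=5, seed=0)

    def test_deterministic_under_seed(self):
        genome = {"chr1": motif_free_genome(30_000, 2)[:10_000] + "GTAC" * 5}
        a = generate_random_is(genome, n=20, seed=9)
        b = generate_random_is(genome, n=20, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = generate_random_is(genome, n=20, seed=10)
        assert not a.equals(c)

    def test_constraint_holds_for_every_site(self, small_sim):
        _, ref, _, _ = small_sim
        sites = generate_random_is(ref.genome, n=200, max_dist=1500, seed=4)
        for _, s in sites.iterrows():
            starts = find_motif_positions(ref.genome[s["chrom"]])
            d = np.min(
                [min(abs(s["pos"] - 1 - m), abs(s["pos"] - 1 - (m + 3))) for m in starts]
            )
            assert d <= 1500

    def test_motif_scan_finds_both_strands(self):
        # GTAC is a palindrome; an asymmetric motif must be found on both
        seq = "AAAAAGGGCCTTTTT"  # GGGCC at 5; revcomp GGCCC absent
        assert list(find_motif_positions(seq, "GGGCC")) == [5]
        assert list(find_motif_positions(seq, "GGCCC")) == [5]


@pytest.fixture
def gene_table():
    return pd.DataFrame(
        {
            "gene_id": ["pc1", "lnc1", "oth1"],
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [10_000, 13_000, 5_000],
            "end": [12_000, 13_500, 6_000],
            "strand": ["+", "-", "+"],
            "biotype": ["protein_coding", "lncRNA", "other"],
        }
    )


def sites_at(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


class TestNearestGene:
    def test_inside_gene_distance_zero(self, gene_table):
        ann = annotate_nearest_gene(sites_at([("chr1", 11_000, "+")]), gene_table)
        assert ann.loc[0, "gene_distance"] == 0
        assert ann.loc[0, "biotype_class"] == "protein_coding"

    def test_beyond_window_is_distal(self, gene_table):
        ann = annotate_nearest_gene(sites_at([("chr2", 7_200, "+")]), gene_table)
        assert ann.loc[0, "gene_distance"] == 1200
        assert ann.loc[0, "biotype_class"] == "distal"

    def test_nearest_wins_regardless_of_priority(self, gene_table):
        # 800 bp from lnc1 end (13500), 900 bp from pc1... position 14300
        ann = annotate_nearest_gene(sites_at([("chr1", 14_300, "+")]), gene_table)
        assert ann.loc[0, "nearest_gene"] == "lnc1"
        assert ann.loc[0, "biotype_class"] == "lncRNA"

    def test_exact_tie_breaks_by_biotype_priority(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["lncA", "pcB"],
                "chrom": ["chr1", "chr1"],
                "start": [1000, 3000],
                "end": [1500, 3500],
                "strand": ["+", "+"],
                "biotype": ["lncRNA", "protein_coding"],
            }
        )
        # position 2250: 750 from both boundaries
        ann = annotate_nearest_gene(sites_at([("chr1", 2250, "+")]), genes)
        assert ann.loc[0, "nearest_gene"] == "pcB"

    def test_no_genes_on_chromosome(self, gene_table):
        ann = annotate_nearest_gene(sites_at([("chr9", 100, "+")]), gene_table)
        assert ann.loc[0, "biotype_class"] == "distal"


class TestActivity:
    def test_strict_threshold(self, gene_table):
        ann = annotate_nearest_gene(
            sites_at([("chr1", 11_000, "+"), ("chr1", 13_200, "-")]), gene_table
        )
        out = classify_activity(ann, {"pc1": 1.0, "lnc1": 7.3})
        assert out.loc[0, "active"] == False  # FPKM exactly 1 is inactive
        assert out.loc[1, "active"] == True

    def test_distal_site_activity_undefined(self, gene_table):
        ann = annotate_nearest_gene(sites_at([("chr2", 9_999, "+")]), gene_table)
        out = classify_activity(ann, {"oth1": 5.0})
        assert out.loc[0, "active"] is None


class TestPeakDistance:
    peaks = {"H3K36me3": pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [1000, 5000], "end": [1600, 5600]}
    )}

    def test_inside_peak_is_zero(self):
        out = peak_distance(sites_at([("chr1", 1300, "+")]), self.peaks)
        assert out.loc[0, "dist_H3K36me3"] == 0

    def test_left_of_peak(self):
        # 1-based 501 -> 0-based 500; peak starts at 1000 -> 500 bp away
        out = peak_distance(sites_at([("chr1", 501, "+")]), self.peaks)
        assert out.loc[0, "dist_H3K36me3"] == 500

    def test_between_peaks_takes_nearest(self):
        out = peak_distance(sites_at([("chr1", 4801, "+")]), self.peaks)
        assert out.loc[0, "dist_H3K36me3"] == 200

    def test_chromosome_without_peaks_is_null(self):
        out = peak_distance(sites_at([("chr2", 100, "+")]), self.peaks)
        assert np.isnan(out.loc[0, "dist_H3K36me3"])

    def test_center_mode(self):
        out = peak_distance(sites_at([("chr1", 1301, "+")]), self.peaks, mode="center")
        assert out.loc[0, "dist_H3K36me3"] == 0


class TestDistanceBinning:
    def test_example_histogram(self):
        h = bin_by_distance([0, 0, 950], bin_width=100, max_dist=1000)
        assert h.iloc[0] == 2
        assert h.iloc[9] == 1
        assert h.sum() == 3

    def test_far_sites_excluded(self):
        h = bin_by_distance([1500, 2000], bin_width=100)
        assert h.sum() == 0

    def test_conservation(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3000, 200).astype(float)
        h = bin_by_distance(d, bin_width=100, max_dist=1000)
        assert h.sum() == (d <= 1000).sum()

    def test_boundary_value_included(self):
        assert bin_by_distance([1000.0]).sum() == 1


class TestChisqYates:
    def test_null_table(self):
        stat, p = chisq_yates(50, 50, 50, 50)
        assert stat == 0.0
        assert p == 1.0

    def test_feature_proximity_table_rejects(self):
        # integration sites near a gene-body mark vs a random null
        stat, p = chisq_yates(486, 411, 116, 884)
        assert p < 0.001

    def test_hand_computed_statistic(self):
        a, b, c, d = 694, 203, 270, 730
        n = a + b + c + d
        expected = n * (abs(a * d - b * c) - n / 2) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        stat, _ = chisq_yates(a, b, c, d)
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            chisq_yates(0, 0, 5, 5)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 200:
            a, b, c, d = rng.integers(1, 500, 4)
            stat, p = chisq_yates(a, b, c, d)
            res = scipy.stats.chi2_contingency([[a, b], [c, d]], correction=True)
            assert stat == pytest.approx(res.statistic, rel=1e-9, abs=1e-12)
            assert p == pytest.approx(res.pvalue, rel=1e-9, abs=1e-12)
            checked += 1


class TestCoverageMatrix:
    lengths = {"chr1": 10_000}

    def test_constant_track(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000], "value": [3.5]})
        cm = coverage_matrix(sites_at([("chr1", 5000, "+")]), track, self.lengths,
                             flank=1000, n_bins=20)
        assert np.allclose(cm.matrix, 3.5)
        assert not cm.clipped[0]

    def test_delta_peak_centered_and_symmetric(self):
        track = pd.DataFrame(
            {"chrom": ["chr1"], "start": [4990], "end": [5010], "value": [100.0]}
        )
        cm = coverage_matrix(sites_at([("chr1", 5001, "+")]), track, self.lengths,
                             flank=1000, n_bins=20)
        prof = cm.profile
        assert prof.argmax() in (9, 10)
        assert prof[0] == prof[-1] == 0

    def test_edge_anchor_clipped_zero_filled(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000], "value": [2.0]})
        cm = coverage_matrix(sites_at([("chr1", 100, "+")]), track, self.lengths,
                             flank=1000, n_bins=20)
        assert cm.clipped[0]
        assert cm.matrix[0, 0] == 0.0  # out-of-range flank
        assert cm.matrix[0, -1] == 2.0

    def test_scale_regions_constant(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000], "value": [1.5]})
        anchors = pd.DataFrame(
            {"chrom": ["chr1"], "start": [4000], "end": [6000]}
        )
        cm = coverage_matrix(anchors, track, self.lengths, flank=1000,
                             n_bins=10, body_bins=20, mode="scale_regions")
        assert cm.matrix.shape == (1, 40)
        assert np.allclose(cm.matrix, 1.5)

    def test_feature_pca_separates_shapes(self):
        flat = np.ones(20)
        peaked = np.ones(20)
        peaked[8:12] = 10.0
        out = feature_pca({"a": flat, "b": flat, "c": peaked})
        assert abs(out.loc["c", "PC1"] - out.loc["a", "PC1"]) > 1.0
        assert out.loc["a", "PC1"] == pytest.approx(out.loc["b", "PC1"])


class TestEnrichment:
    def test_planted_sites_enrich(self):
        vis = np.zeros(100)  # all inside peaks
        rand = np.concatenate([np.zeros(12), np.full(88, 5000.0)])
        res = proximity_enrichment(vis, rand)
        assert res["vis_pct"] == 100.0
        assert res["p_value"] < 0.001
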