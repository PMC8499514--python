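import numpy as np
import pandas as pd
import pytest

from lovis.vis_quantifier import (
    SITE_KEY,
    ClonalMatrix,
    aggregate_sites,
    compute_frequencies,
    correct_collisions,
    correct_signal_crossover,
    filter_min_count,
    merge_replicates,
)


def make_samples(ids, animal="m1"):
    return pd.DataFrame(
        {
            "sample_id": ids,
            "animal": animal,
            "timepoint": 13,
            "tissue": "blood",
            "replicate": [f"r{i+1}" for i in range(len(ids))],
            "population": "mixed",
        }
    ).set_index("sample_id")


def make_calls(rows, sample="s1"):
    """rows: (chrom, pos, strand, index_label) of accepted reads."""
    df = pd.DataFrame(rows, columns=SITE_KEY)
    df["sample_id"] = sample
    df["status"] = "accepted"
    df["read_id"] = [f"r{i}" for i in range(len(df))]
    return df


def matrix_from_counts(counts: dict, samples):
    """counts: site key tuple -> list of per-sample counts."""
    idx = pd.MultiIndex.from_tuples(list(counts), names=SITE_KEY)
    return ClonalMatrix(
        pd.DataFrame(list(counts.values()), index=idx, columns=samples.index),
        samples,
    )


class TestAggregateSites:
    def test_jittered_positions_merge_at_modal(self):
        calls = make_calls([("chr1", p, "+", "H5") for p in (1000, 1002, 1000)])
        m = aggregate_sites(calls, make_samples(["s1"]), merge_window=5)
        assert list(m.counts.index) == [("chr1", 1000, "+", "H5")]
        assert m.counts.iloc[0, 0] == 3

    def test_distant_positions_stay_separate(self):
        calls = make_calls([("chr1", 1000, "+", "H5"), ("chr1", 1010, "+", "H5")])
        m = aggregate_sites(calls, make_samples(["s1"]), merge_window=5)
        assert m.n_sites == 2

    def test_opposite_strands_are_distinct_sites(self):
        calls = make_calls([("chr1", 1000, "+", "H5"), ("chr1", 1000, "-", "H5")])
        m = aggregate_sites(calls, make_samples(["s1"]), merge_window=5)
        assert m.n_sites == 2

    def test_modal_tie_breaks_to_smallest(self):
        calls = make_calls([("chr1", 1000, "+", "H5"), ("chr1", 1003, "+", "H5")])
        m = aggregate_sites(calls, make_samples(["s1"]), merge_window=5)
        assert list(m.counts.index) == [("chr1", 1000, "+", "H5")]

    def test_empty_input_gives_empty_matrix(self):
        calls = make_calls([]).iloc[0:0]
        m = aggregate_sites(calls, make_samples(["s1"]))
        assert m.n_sites == 0


class TestCrossover:
    def test_minor_label_folded_into_major(self):
        samples = make_samples(["s1"])
        m = matrix_from_counts(
            {("chr1", 100, "+", "H5"): [500], ("chr1", 100, "+", "WT"): [3]}, samples
        )
        out = correct_signal_crossover(m, ratio=0.1)
        assert list(out.counts.index) == [("chr1", 100, "+", "H5")]
        assert out.counts.iloc[0, 0] == 503

    def test_balanced_labels_kept_distinct(self):
        samples = make_samples(["s1"])
        m = matrix_from_counts(
            {("chr1", 100, "+", "H5"): [300], ("chr1", 100, "+", "WT"): [200]}, samples
        )
        out = correct_signal_crossover(m, ratio=0.1)
        assert out.n_sites == 2

    def test_single_label_unchanged(self):
        samples = make_samples(["s1"])
        m = matrix_from_counts({("chr1", 100, "+", "H5"): [50]}, samples)
        out = correct_signal_crossover(m)
        pd.testing.assert_frame_equal(out.counts, m.counts)

    def test_total_count_preserved(self):
        samples = make_samples(["s1", "s2"])
        m = matrix_from_counts(
            {
                ("chr1", 100, "+", "H5"): [500, 400],
                ("chr1", 100, "+", "WT"): [3, 5],
                ("chr2", 9, "-", "WT"): [7, 7],
            },
            samples,
        )
        out = correct_signal_crossover(m)
        assert out.counts.to_numpy().sum() == m.counts.to_numpy().sum()


class TestCollisions:
    def test_dominant_animal_keeps_site(self):
        a = matrix_from_counts({("chr1", 100, "+", "H5"): [400]}, make_samples(["a1"], "A"))
        b = matrix_from_counts({("chr1", 100, "+", "H5"): [5]}, make_samples(["b1"], "B"))
        out = correct_collisions({"A": a, "B": b}, ratio=0.1)
        assert out["A"].n_sites == 1
        assert out["B"].n_sites == 0

    def test_no_dominance_removes_everywhere(self):
        a = matrix_from_counts({("chr1", 100, "+", "H5"): [100]}, make_samples(["a1"], "A"))
        b = matrix_from_counts({("chr1", 100, "+", "H5"): [90]}, make_samples(["b1"], "B"))
        out = correct_collisions({"A": a, "B": b}, ratio=0.1)
        assert out["A"].n_sites == 0
        assert out["B"].n_sites == 0

    def test_private_site_unchanged(self):
        a = matrix_from_counts({("chr1", 100, "+", "H5"): [100]}, make_samples(["a1"], "A"))
        b = matrix_from_counts({("chr2", 200, "-", "WT"): [90]}, make_samples(["b1"], "B"))
        out = correct_collisions({"A": a, "B": b})
        assert out["A"].n_sites == 1 and out["B"].n_sites == 1

    def test_collision_matching_ignores_index_label(self):
        # same coordinate under different labels is still one collision
        a = matrix_from_counts({("chr1", 100, "+", "H5"): [400]}, make_samples(["a1"], "A"))
        b = matrix_from_counts({("chr1", 100, "+", "WT"): [5]}, make_samples(["b1"], "B"))
        out = correct_collisions({"A": a, "B": b})
        assert out["B"].n_sites == 0

    def test_corrections_never_increase_totals(self):
        a = matrix_from_counts(
            {("chr1", 100, "+", "H5"): [100], ("chr1", 500, "+", "H5"): [30]},
            make_samples(["a1"], "A"),
        )
        b = matrix_from_counts({("chr1", 100, "+", "H5"): [90]}, make_samples(["b1"], "B"))
        before = a.counts.to_numpy().sum() + b.counts.to_numpy().sum()
        out = correct_collisions({"A": a, "B": b})
        after = sum(m.counts.to_numpy().sum() for m in out.values())
        assert after <= before


class TestMinCountFilter:
    def test_below_threshold_removed_boundary_kept(self):
        samples = make_samples(["s1", "s2", "s3", "s4"])
        m = matrix_from_counts(
            {
                ("chr1", 1, "+", "H5"): [1, 1, 1, 0],  # total 3 < 4
                ("chr1", 9, "+", "H5"): [1, 1, 1, 1],  # total 4, kept (strict rule)
            },
            samples,
        )
        out = filter_min_count(m, 4)
        assert list(out.counts.index) == [("chr1", 9, "+", "H5")]

    def test_n_samples_one_drops_only_zero_sites(self):
        samples = make_samples(["s1"])
        m = matrix_from_counts(
            {("chr1", 1, "+", "H5"): [0], ("chr1", 9, "+", "H5"): [1]}, samples
        )
        out = filter_min_count(m, 1)
        assert out.n_sites == 1

    def test_invalid_sample_count_raises(self):
        m = matrix_from_counts({("chr1", 1, "+", "H5"): [5]}, make_samples(["s1"]))
        with pytest.raises(ValueError, match="invalid sample count"):
            filter_min_count(m, 0)

    def test_idempotent(self):
        samples = make_samples(["s1", "s2"])
        m = matrix_from_counts(
            {("chr1", 1, "+", "H5"): [1, 0], ("chr1", 9, "+", "H5"): [5, 5]}, samples
        )
        once = filter_min_count(m, 2)
        twice = filter_min_count(once, 2)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestFrequencies:
    def test_proportions(self):
        samples = make_samples(["s1"])
        m = matrix_from_counts(
            {
                ("chr1", 1, "+", "H5"): [10],
                ("chr1", 9, "+", "H5"): [30],
                ("chr2", 5, "-", "WT"): [60],
            },
            samples,
        )
        p = compute_frequencies(m).p
        assert sorted(p["s1"]) == pytest.approx([0.1, 0.3, 0.6])

    def test_columns_sum_to_one(self, small_result):
        for prof in small_result["frequencies"].values():
            sums = prof.p.sum(axis=0)
            nonempty = [s for s in sums.index if s not in prof.empty_samples]
            assert np.allclose(sums[nonempty], 1.0, atol=1e-9)

    def test_empty_sample_flagged(self):
        samples = make_samples(["s1", "s2"])
        m = matrix_from_counts({("chr1", 1, "+", "H5"): [4, 0]}, samples)
        prof = compute_frequencies(m)
        assert prof.empty_samples == ("s2",)
        assert (prof.p["s2"] == 0).all()


class TestMergeReplicates:
    def test_identical_replicates_mean_frequency(self):
        samples = make_samples(["s1", "s2"])
        m = matrix_from_counts(
            {("chr1", 1, "+", "H5"): [10, 10], ("chr1", 9, "+", "H5"): [30, 30]}, samples
        )
        prof = merge_replicates(m, "mean_frequency")
        assert sorted(prof.p.iloc[:, 0]) == pytest.approx([0.25, 0.75])

    def test_sum_counts_adds_columns(self):
        samples = make_samples(["s1", "s2"])
        m = matrix_from_counts(
            {("chr1", 1, "+", "H5"): [10, 0], ("chr1", 9, "+", "H5"): [0, 10]}, samples
        )
        out = merge_replicates(m, "sum_counts")
        assert list(out.counts.iloc[:, 0]) == [10, 10]

    def test_one_empty_replicate_sum_equals_other(self):
        samples = make_samples(["s1", "s2"])
        m = matrix_from_counts(
            {("chr1", 1, "+", "H5"): [7, 0], ("chr1", 9, "+", "H5"): [3, 0]}, samples
        )
        out = merge_replicates(m, "sum_counts")
        assert list(out.counts.iloc[:, 0]) == [7, 3]

    def test_missing_replicate_id_names_sample(self):
        samples = make_samples(["s1", "s2"])
        samples.loc["s2", "replicate"] = np.nan
        m = matrix_from_counts({("chr1", 1, "+", "H5"): [1, 1]}, samples)
        with pytest.raises(ValueError, match="s2"):
            merge_replicates(m, "sum_counts")
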