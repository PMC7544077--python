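import numpy as np
import pytest

from rhythmclust import (
    DEFAULT_PAIRS,
    WindowSpec,
    bh_adjust,
    compare_representations,
    delong_test,
    roc_auc,
    run_grid,
)
from rhythmclust.evaluation import roc_auc_ids, same_partition
from conftest import make_seq
from oracles import auc_pair_counting, bh_stepup


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 4], [1, 1, 2, 2])
        assert r.auc_raw == 1.0 and r.auc_oriented == 1.0

    def test_tied_worked_example(self):
        r = roc_auc([1, 2, 2, 3], [1, 1, 2, 2])
        assert r.auc_raw == pytest.approx(0.875)

    def test_complete_ties_give_half(self):
        r = roc_auc([2, 2, 2, 2], [1, 2, 1, 2])
        assert r.auc_raw == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 31))
            scores = rng.integers(0, 5, size=n).astype(float)
            labels = np.ones(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 2
            if not (labels == 1).any():
                continue
            r = roc_auc(scores, labels)
            expected = auc_pair_counting(scores[labels == 2], scores[labels == 1])
            assert r.auc_raw == pytest.approx(expected, abs=1e-12)

    def test_orientation_invariant_to_label_swap(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(1, 3, size=30)
        labels[0], labels[1] = 1, 2
        a = roc_auc(scores, labels)
        b = roc_auc(scores, 3 - labels)
        assert a.auc_oriented == pytest.approx(b.auc_oriented, abs=1e-12)
        assert a.auc_raw == pytest.approx(1 - b.auc_raw, abs=1e-12)

    def test_empty_cluster_after_filtering_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc_auc([np.nan, 2.0, 3.0], [1, 2, 2])

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=50)
        labels = rng.integers(1, 3, size=50)
        labels[:2] = [1, 2]
        r = roc_auc(scores, labels)
        assert r.auc_raw == pytest.approx(roc_auc_score(labels == 2, scores), abs=1e-12)

    def test_hanley_mcneil_variance_sanity(self, rng):
        """DeLong variance within 20% of the Hanley-McNeil closed form on
        tie-free normal-shift data."""
        m = n = 60
        reps = 200
        ratio = []
        for _ in range(reps):
            x = rng.normal(0.8, 1, size=m)
            y = rng.normal(0.0, 1, size=n)
            scores = np.concatenate([x, y])
            labels = np.array([2] * m + [1] * n)
            r = roc_auc(scores, labels)
            a = r.auc_raw
            q1, q2 = a / (2 - a), 2 * a**2 / (1 + a)
            hm = (a * (1 - a) + (m - 1) * (q1 - a**2) + (n - 1) * (q2 - a**2)) / (m * n)
            if hm > 0:
                ratio.append(r.variance / hm)
        assert 0.8 < np.median(ratio) < 1.2


class TestDelong:
    def test_self_comparison_is_null(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(1, 3, size=40)
        labels[:2] = [1, 2]
        r = roc_auc(scores, labels)
        z, p = delong_test(r, r, paired=True)
        assert z == 0.0 and p == 1.0

    def test_paired_requires_same_partition(self, rng):
        scores = rng.normal(size=20)
        la = np.array([1] * 10 + [2] * 10)
        lb = np.array([1] * 12 + [2] * 8)
        a = roc_auc(scores, la)
        b = roc_auc(scores, lb)
        assert not same_partition(a, b)
        with pytest.raises(ValueError, match="paired=False"):
            delong_test(a, b, paired=True)

    def test_null_rejection_rate_quick(self, rng):
        """Smaller replicate count than the full calibration run."""
        rejections = 0
        reps = 400
        labels = np.array([1] * 50 + [2] * 50)
        for _ in range(reps):
            a = roc_auc(rng.normal(size=100), labels)
            b = roc_auc(rng.normal(size=100), labels)
            _, p = delong_test(a, b, paired=False)
            rejections += p < 0.05
        assert 0.02 < rejections / reps < 0.09

    def test_unpaired_agrees_with_bootstrap_oracle(self):
        rng = np.random.default_rng(777)
        labels = np.array([1] * 60 + [2] * 60)
        sa = np.concatenate([rng.normal(0, 1, 60), rng.normal(0.9, 1, 60)])
        sb = np.concatenate([rng.normal(0, 1, 60), rng.normal(0.5, 1, 60)])
        a = roc_auc(sa, labels)
        b = roc_auc(sb, labels)
        _, p = delong_test(a, b, paired=False)

        boots = 10_000
        diffs = np.empty(boots)
        for i in range(boots):
            ia = np.concatenate([rng.integers(0, 60, 60), 60 + rng.integers(0, 60, 60)])
            ib = np.concatenate([rng.integers(0, 60, 60), 60 + rng.integers(0, 60, 60)])
            da = roc_auc(sa[ia], labels).auc_raw
            db = roc_auc(sb[ib], labels).auc_raw
            diffs[i] = da - db
        # symmetric percentile test of H0: no AUC difference
        p_boot = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert p == pytest.approx(p_boot, abs=0.02)


class TestBhAdjust:
    def test_hand_trace(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    def test_matches_textbook_stepup(self, rng):
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 21)))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup(p), atol=1e-12)

    def test_inflation_property(self, rng):
        p = rng.uniform(size=10)
        assert np.all(bh_adjust(p) >= p - 1e-15)


class TestGrid:
    def test_full_grid_cell_count(self, small_dataset):
        grid = run_grid(small_dataset, WindowSpec(45, 5))
        assert len(grid.results) + len(grid.errors) == 90

    def test_per_representation_is_15(self, small_dataset):
        grid = run_grid(small_dataset, WindowSpec(45, 5), representations=["stacf_raw"])
        assert len(grid.results) + len(grid.errors) == 15

    def test_identical_sequences_give_error_cells_not_crashes(self):
        from rhythmclust import LabeledDataset

        seqs = [make_seq(np.sin(np.arange(60.0) / 5), sid=f"s{i}", score=float(i % 2)) for i in range(4)]
        ds = LabeledDataset(seqs)
        grid = run_grid(ds, WindowSpec(45, 5), distances=["euclid"], linkages=["complete"])
        # all-zero distance matrices cluster degenerately; cells must be
        # recorded one way or the other, without raising
        assert len(grid.results) + len(grid.errors) == 6

    def test_rerun_identical(self, small_dataset):
        g1 = run_grid(small_dataset, WindowSpec(45, 5), distances=["dtw"], linkages=["ward_d"])
        g2 = run_grid(small_dataset, WindowSpec(45, 5), distances=["dtw"], linkages=["ward_d"])
        for key in g1.results:
            assert g1.results[key].auc_raw == g2.results[key].auc_raw

    def test_unscored_sequences_dropped_with_count(self, small_dataset):
        from rhythmclust import LabeledDataset

        extra = make_seq(np.sin(np.arange(60.0) / 4), sid="zz_unscored", score=None)
        ds = LabeledDataset(list(small_dataset) + [extra])
        grid = run_grid(ds, WindowSpec(45, 5), representations=["raw"], distances=["euclid"], linkages=["complete"])
        assert grid.n_dropped_unscored == 1
        (res,) = grid.results.values()
        assert res.n1 + res.n2 == len(small_dataset)


class TestCompareRepresentations:
    def test_four_pairs_with_bh_over_four(self, small_dataset):
        grid = run_grid(small_dataset, WindowSpec(45, 5), distances=["dtw"], linkages=["ward_d"])
        result = compare_representations(grid, "dtw", "ward_d")
        assert len(result.rows) == 4
        assert [r.pair for r in result.rows] == [f"{a}_vs_{b}" for a, b in DEFAULT_PAIRS]
        raw_p = [r.p for r in result.rows]
        np.testing.assert_allclose([r.p_fdr for r in result.rows], bh_stepup(raw_p), atol=1e-12)
        for r in result.rows:
            assert r.significant == (r.p_fdr < 0.05)

    def test_missing_cell_names_condition(self, small_dataset):
        grid = run_grid(small_dataset, WindowSpec(45, 5), representations=["raw"],
                        distances=["dtw"], linkages=["ward_d"])
        with pytest.raises(ValueError, match="stacf_raw"):
            compare_representations(grid, "dtw", "ward_d")

    def test_self_pair_is_null(self, small_dataset):
        grid = run_grid(small_dataset, WindowSpec(45, 5), distances=["dtw"], linkages=["ward_d"])
        result = compare_representations(
            grid, "dtw", "ward_d", pairs=[("stacf_raw", "stacf_raw")]
        )
        assert result.rows[0].p == 1.0 and result.rows[0].p_fdr == 1.0
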