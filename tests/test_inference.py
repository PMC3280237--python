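"""Permutation tests, outcome t-test and ROC/AUC."""

import itertools

import numpy as np
import pytest
from scipy import stats

from brainrisk.inference import (
    PermutationConfig,
    _pvalue,
    auc_permutation_pvalue,
    permutation_pvalue,
    permute_labels,
    roc_curve,
    ttest_outcome,
)


def brute_force_auc(scores, labels):
    """Pairwise-comparison oracle: P(score_pos > score_neg), ties half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestPValueRule:
    def test_paper_style_count(self):
        """8 of 1000 permutations beating the observed statistic gives 0.008."""
        permuted = np.concatenate([np.full(8, 90.0), np.full(992, 40.0)])
        assert _pvalue(75.0, permuted, "strictly_greater") == 0.008

    def test_observed_above_all_gives_zero_under_strict_rule(self):
        assert _pvalue(99.0, np.full(100, 50.0), "strictly_greater") == 0.0

    def test_greater_or_equal_uses_n_plus_one(self):
        assert _pvalue(99.0, np.full(99, 50.0), "greater_or_equal") == 0.01

    def test_mid_p_counts_ties_half(self):
        permuted = np.array([10.0, 50.0, 50.0, 90.0])
        assert _pvalue(50.0, permuted, "mid_p") == (1 + 0.5 * 2) / 4


class TestPermutationMachinery:
    def test_within_pair_flip_preserves_pairing(self, rng):
        y = np.array([1, -1] * 6)
        pairs = np.repeat([f"p{i}" for i in range(6)], 2)
        y_new = permute_labels(y, pairs, "within_pair_flip", rng)
        for pid in np.unique(pairs):
            assert sorted(y_new[pairs == pid]) == [-1, 1]

    def test_free_relabel_preserves_counts(self, rng):
        y = np.array([1, -1] * 6)
        y_new = permute_labels(y, np.repeat(np.arange(6), 2), "free_relabel", rng)
        assert np.sum(y_new == 1) == 6

    def test_monte_carlo_converges_to_exhaustive_flip_pvalue(self, null_data):
        """With 3 pairs the 2^3 within-pair relabelings can be enumerated; the
        sampled p-value must approach the exhaustive one."""
        from brainrisk.data_io import BrainMask, FeatureDataset

        ds = null_data.datasets["neutral"]
        rows = np.isin(ds.pairs, np.unique(ds.pairs)[:3])
        X, y, pairs = ds.X[rows, :5], ds.y[rows], ds.pairs[rows]

        def stat(dataset):
            return float(dataset.X[dataset.y == 1].mean()
                         - dataset.X[dataset.y == -1].mean())

        mask = BrainMask.from_array(np.ones((5, 1, 1)), np.eye(4))
        small = FeatureDataset(X=X, y=y, pairs=pairs, mask=mask,
                               condition="neutral")
        observed = stat(small)
        exhaustive = []
        for flips in itertools.product([False, True], repeat=3):
            y_f = y.copy()
            for flip, pid in zip(flips, np.unique(pairs)):
                if flip:
                    r = np.flatnonzero(pairs == pid)
                    y_f[r] = y_f[r][::-1]
            exhaustive.append(stat(FeatureDataset(
                X=X, y=y_f, pairs=pairs, mask=mask, condition="neutral")))
        p_exact = np.mean(np.array(exhaustive) > observed)

        res = permutation_pvalue(
            small, stat,
            PermutationConfig(n_permutations=4000, seed=9,
                              scheme="within_pair_flip"))
        assert res.p_value == pytest.approx(p_exact, abs=0.03)

    def test_reproducible_for_fixed_seed(self, null_data):
        ds = null_data.datasets["neutral"]
        cfg = PermutationConfig(n_permutations=20, seed=5)
        stat = lambda d: float(d.X[d.y == 1].mean())
        r1 = permutation_pvalue(ds, stat, cfg)
        r2 = permutation_pvalue(ds, stat, cfg)
        assert np.array_equal(r1.permuted_statistics, r2.permuted_statistics)


class TestOutcomeTTest:
    def test_degrees_of_freedom_for_six_vs_seven(self, rng):
        res = ttest_outcome(rng.random(6), rng.random(7))
        assert res.degrees_of_freedom == 11

    def test_symmetric_groups_give_t_zero(self):
        res = ttest_outcome([0.4, 0.5, 0.6], [0.5, 0.6, 0.4])
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value_one_tailed == pytest.approx(0.5, abs=1e-12)

    def test_matches_reference_implementation(self):
        dev = np.array([0.9, 0.8, 0.85])
        nondev = np.array([0.5, 0.55, 0.45])
        res = ttest_outcome(dev, nondev)
        t_ref, p_ref = stats.ttest_ind(dev, nondev, alternative="greater")
        assert res.t_statistic == pytest.approx(float(t_ref), abs=1e-6)
        assert res.p_value_one_tailed == pytest.approx(float(p_ref), abs=1e-6)
        assert res.group_means == (pytest.approx(0.85), pytest.approx(0.5))

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ttest_outcome([0.5, 0.5], [0.5, 0.5])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ttest_outcome([0.5], [0.4, 0.6])


class TestROC:
    def test_perfect_separation(self):
        assert roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == 1.0

    def test_all_tied_scores(self):
        assert roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == 0.5

    def test_example_against_brute_force(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.2]
        labels = [1, 0, 1, 0, 1]
        res = roc_curve(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            res = roc_curve(scores, labels)
            assert res.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_curve_endpoints_and_monotonicity(self, rng):
        res = roc_curve(rng.random(15), rng.integers(0, 2, 15) | (np.arange(15) == 0))
        pts = res.points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20) | (np.arange(20) == 0)
        a1 = roc_curve(scores, labels).auc
        a2 = roc_curve(np.exp(3 * scores) - 1, labels).auc
        assert a1 == pytest.approx(a2)

    def test_complement_identity_for_tie_free_scores(self, rng):
        scores = rng.permutation(20).astype(float)
        labels = (np.arange(20) < 8).astype(int)
        assert (roc_curve(scores, labels).auc
                + roc_curve(-scores, labels).auc) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_curve([0.1, 0.2], [1, 1])


class TestAUCPermutation:
    def test_perfect_separation_is_significant(self, rng):
        scores = np.concatenate([rng.random(6) + 2, rng.random(7)])
        labels = np.array([1] * 6 + [0] * 7)
        res = auc_permutation_pvalue(
            scores, labels, PermutationConfig(n_permutations=1000, seed=3))
        assert res.observed_statistic == 1.0
        assert res.p_value <= 0.01

    def test_single_permutation_gives_zero_or_one(self, rng):
        scores = rng.random(10)
        labels = np.array([1] * 5 + [0] * 5)
        res = auc_permutation_pvalue(
            scores, labels, PermutationConfig(n_permutations=1, seed=0))
        assert res.p_value in (0.0, 1.0)

    def test_pvalues_uniform_under_null(self, rng):
        """With labels independent of scores, (count+1)/(N+1) p-values are
        uniform on {1/100, ..., 1}; a KS test should not reject at alpha=0.01."""
        pvals = []
        for k in range(200):
            scores = rng.random(13)
            labels = np.array([1] * 6 + [0] * 7)
            res = auc_permutation_pvalue(
                scores, labels,
                PermutationConfig(n_permutations=99, seed=10_000 + k,
                                  comparison="greater_or_equal"))
            pvals.append(res.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
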