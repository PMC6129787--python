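"""Microstate clustering, pseudo statistics and class-count selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mstate import synth
from mstate.cluster import (CVResult, PeakPartition, TemplateSet,
                            cross_validate_k, explained_variance,
                            kmeans_microstates, kmeans_objective,
                            normalize_maps, pseudo_F, pseudo_stat_curves,
                            pseudo_t2, select_k, spatial_correlation)
from mstate.gfp import PeakSet, compute_gfp, find_gfp_peaks
from mstate.io_preprocess import Recording


class TestSpatialCorrelation:
    def test_identical_maps(self):
        m = np.array([1.0, -2.0, 3.0, 0.5])
        assert spatial_correlation(m, m) == pytest.approx(1.0)

    def test_negation_folds_in_invariant_mode(self):
        m = np.array([1.0, -2.0, 3.0, 0.5])
        assert spatial_correlation(m, -m, "signed") == pytest.approx(-1.0)
        assert spatial_correlation(m, -m, "invariant") == pytest.approx(1.0)

    def test_orthogonal_zero_mean_maps(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert spatial_correlation(a, b, "signed") == pytest.approx(0.0)

    def test_zero_variance_map_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(4), np.array([1.0, 2, 3, 4]))


class TestKmeans:
    def test_k1_single_class(self):
        rng = np.random.default_rng(0)
        maps = rng.normal(size=(20, 9))
        tmpl, part = kmeans_microstates(maps, 1, seed=0)
        assert tmpl.k == 1
        assert set(part.assignments) == {0}
        assert part.n_p[0] == 20

    def test_recovers_orthogonal_planted_classes_exactly(self):
        """Noiseless maps from 3 orthogonal templates are perfectly
        reassigned (up to label permutation)."""
        base = np.array([[1, -1, 0, 0, 1, -1, 0, 0, 0],
                        [1, 1, -1, -1, 0, 0, 0, 0, 0],
                        [0, 0, 0, 0, 1, 1, -1, -1, 0]], dtype=float)
        base = normalize_maps(base)
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 3, size=60)
        scales = rng.uniform(0.5, 3.0, size=60)
        signs = rng.choice([-1.0, 1.0], size=60)
        maps = base[truth] * (scales * signs)[:, None]
        _, part = kmeans_microstates(maps, 3, seed=2)
        # same partition as truth, up to relabeling
        relabel = {}
        for t, a in zip(truth, part.assignments):
            relabel.setdefault(t, a)
            assert relabel[t] == a

    def test_matches_exhaustive_best_partition_on_four_maps(self):
        """k-means on 4 maps equals the best of all signed 2-class
        assignments by total within-class similarity (exhaustive oracle)."""
        rng = np.random.default_rng(3)
        maps = normalize_maps(rng.normal(size=(4, 9)))

        def objective(assign):
            total = 0.0
            for c in (0, 1):
                sub = maps[np.array(assign) == c]
                if sub.shape[0] == 0:
                    return -np.inf
                cov = sub.T @ sub
                w, vecs = np.linalg.eigh(cov)
                t = normalize_maps(vecs[:, -1][None, :])[0]
                total += float((((sub @ t) / 9) ** 2).sum())
            return total

        best = max(objective(a) for a in itertools.product((0, 1), repeat=4))
        tmpl, _ = kmeans_microstates(maps, 2, n_restarts=20, seed=4)
        got = kmeans_objective(maps, tmpl)
        assert got == pytest.approx(best, rel=1e-9)

    def test_objective_monotone_in_iterations(self):
        rng = np.random.default_rng(5)
        maps = rng.normal(size=(40, 9))
        objs = []
        for it in range(1, 8):
            tmpl, _ = kmeans_microstates(maps, 3, n_restarts=1, seed=6,
                                         max_iter=it)
            objs.append(kmeans_objective(maps, tmpl))
        assert np.all(np.diff(objs) >= -1e-9)

    def test_k_exceeding_peak_count_rejected(self):
        with pytest.raises(ValueError):
            kmeans_microstates(np.random.default_rng(0).normal(size=(3, 9)),
                               5, seed=0)

    def test_deterministic_given_seed(self):
        maps = np.random.default_rng(7).normal(size=(30, 9))
        a = kmeans_microstates(maps, 3, seed=11)
        b = kmeans_microstates(maps, 3, seed=11)
        np.testing.assert_array_equal(a[0].maps, b[0].maps)
        np.testing.assert_array_equal(a[1].assignments, b[1].assignments)


class TestPseudoStatistics:
    def test_pseudo_f_hand_computation(self):
        # 1-D points {0,1,10,11}: T = 101, P = 1, F = (100/1)/(1/2) = 200
        part = PeakPartition.from_points(np.array([0.0, 1.0, 10.0, 11.0]),
                                         np.array([0, 0, 1, 1]))
        assert part.total_ss == pytest.approx(101.0)
        assert part.pooled_within == pytest.approx(1.0)
        assert pseudo_F(part) == pytest.approx(200.0)

    def test_pseudo_f_degenerate_cases(self):
        same = PeakPartition.from_points(np.zeros(6), np.array([0, 0, 0, 1, 1, 1]))
        assert pseudo_F(same) == 0.0
        perfect = PeakPartition.from_points(
            np.array([0.0, 0.0, 5.0, 5.0]), np.array([0, 0, 1, 1]))
        assert pseudo_F(perfect) == np.inf
        with pytest.raises(ValueError):
            pseudo_F(PeakPartition.from_points(np.arange(5.0), np.zeros(5, int)))

    def test_pseudo_f_matches_brute_force_on_random_points(self):
        """Scatter decomposition equals an explicit loop oracle (≤ 12 pts)."""
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 3))
        assign = rng.integers(0, 3, size=12)
        while len(set(assign)) < 3:
            assign = rng.integers(0, 3, size=12)
        part = PeakPartition.from_points(pts, assign)
        grand = pts.mean(axis=0)
        T = sum(float((p - grand) @ (p - grand)) for p in pts)
        P = 0.0
        for c in range(3):
            sub = pts[assign == c]
            mu = sub.mean(axis=0)
            P += sum(float((p - mu) @ (p - mu)) for p in sub)
        expected = ((T - P) / 2) / (P / 9)
        assert pseudo_F(part) == pytest.approx(expected, rel=1e-12)

    def test_pseudo_t2_hand_computation(self):
        # {0,1} vs {10,11}: Wp = Wq = 0.5, W_merged = 101, B² = 100,
        # t² = 100 / ((1)/2) = 200
        assert pseudo_t2(np.array([0.0, 1.0]), np.array([10.0, 11.0])) == \
            pytest.approx(200.0)

    def test_pseudo_t2_identical_clusters(self):
        assert pseudo_t2(np.array([2.0, 2.0]), np.array([2.0, 2.0])) == 0.0

    def test_pseudo_t2_requires_enough_points(self):
        with pytest.raises(ValueError):
            pseudo_t2(np.array([1.0]), np.array([2.0]))

    def test_merge_statistic_collapses_beyond_true_k(self):
        """With 3 well-separated (orthogonal) planted classes, the k=3 merge
        statistic is cluster-scale while the k=4 merge — re-joining the two
        halves of a split class — is an order of magnitude smaller."""
        from mstate.cluster import normalize_maps
        base = normalize_maps(np.array(
            [[1, -1, 0, 0, 1, -1, 0, 0, 0],
             [1, 1, -1, -1, 0, 0, 0, 0, 0],
             [0, 0, 0, 0, 1, 1, -1, -1, 0]], dtype=float))
        rng = np.random.default_rng(6)
        truth = rng.integers(0, 3, size=240)
        maps = base[truth] * rng.uniform(0.7, 2.0, (240, 1)) \
            + rng.normal(0, 0.25, (240, 9))
        curves = pseudo_stat_curves(maps, [2, 3, 4, 5], seed=0)
        t2 = curves.set_index("k")["pseudo_t2"]
        assert t2[3] > 5 * t2[4]


class TestCrossValidation:
    def _peaks(self, maps, strata=None):
        return PeakSet(indices=np.arange(maps.shape[0]), maps=maps,
                       gfp_at_peak=np.ones(maps.shape[0]), strata=strata)

    def test_same_seed_reproduces_per_rep_matrix(self):
        maps = np.random.default_rng(9).normal(size=(60, 9))
        p = self._peaks(maps)
        a = cross_validate_k(p, range(1, 4), n_reps=5, seed=3)
        b = cross_validate_k(p, range(1, 4), n_reps=5, seed=3)
        np.testing.assert_array_equal(a.per_rep_corr, b.per_rep_corr)

    def test_single_planted_template_selects_one_class(self, templates3):
        rng = np.random.default_rng(10)
        maps = templates3.maps[0][None, :] * rng.uniform(0.5, 2, (120, 1)) \
            + rng.normal(0, 0.15, (120, 9))
        p = self._peaks(maps)
        cv = cross_validate_k(p, range(1, 6), n_reps=20, seed=4)
        sel = select_k(cv)
        assert sel.k == 1

    def test_stratum_too_small_rejected(self):
        maps = np.random.default_rng(11).normal(size=(10, 9))
        p = self._peaks(maps, strata=np.array(["a"] * 9 + ["b"]))
        with pytest.raises(ValueError, match="stratum"):
            cross_validate_k(p, [1, 2], n_reps=1, seed=0)


class TestSelectK:
    def _cv(self, ks, mc):
        mc = np.asarray(mc, dtype=float)
        return CVResult(k_values=np.asarray(ks), mean_corr=mc,
                        per_rep_corr=mc[None, :], n_reps=1, train_frac=0.8,
                        seed=0)

    def test_all_criteria_agree_on_three(self):
        cv = self._cv([1, 2, 3, 4, 5], [0.5, 0.7, 0.9, 0.903, 0.905])
        curves = pd.DataFrame({"k": [2, 3, 4, 5],
                               "pseudo_F": [300.0, 500.0, 320.0, 250.0],
                               "pseudo_t2": [200.0, 180.0, 15.0, 12.0]})
        sel = select_k(cv, curves)
        assert sel.k == 3 and sel.agree

    def test_flat_cv_defers_to_pseudo_f(self):
        cv = self._cv([1, 2, 3, 4], [0.9, 0.9, 0.9, 0.9])
        curves = pd.DataFrame({"k": [2, 3, 4],
                               "pseudo_F": [500.0, 300.0, 200.0],
                               "pseudo_t2": [90.0, 80.0, 70.0]})
        sel = select_k(cv, curves)
        assert sel.k == 2
        assert sel.cv_k is None
        assert not sel.agree

    def test_literal_sign_change_rule(self):
        cv = self._cv([2, 3, 4, 5], [0.7, 0.9, 0.901, 0.902])
        curves = pd.DataFrame({"k": [2, 3, 4, 5],
                               "pseudo_F": [300.0, 500.0, 320.0, 250.0],
                               "pseudo_t2": [100.0, 15.2, -14.7, -3.0]})
        sel = select_k(cv, curves)
        assert sel.pseudo_t2_k == 3

    def test_singleton_k_range(self):
        sel = select_k(self._cv([1], [0.8]))
        assert sel.k == 1


def test_explained_variance_of_clean_maps_is_100(templates3):
    rng = np.random.default_rng(12)
    truth = rng.integers(0, 3, 50)
    maps = templates3.maps[truth] * rng.uniform(0.5, 2.0, (50, 1))
    p = PeakSet(indices=np.arange(50), maps=maps,
                gfp_at_peak=maps.std(axis=1, ddof=0))
    t = TemplateSet(maps=templates3.maps)
    assert explained_variance(p, t) == pytest.approx(100.0, abs=1e-9)
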