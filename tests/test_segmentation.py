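import numpy as np
import pytest

from eegtopo import (
    UNASSIGNED,
    aahc,
    cross_validation,
    dispersion_curve,
    gev,
    kl_criterion,
    merge_clusters,
    modified_kmeans,
    reject_small_segments,
    sequentialize,
    smooth_labels,
)
from eegtopo.segmentation import DispersionCurve


def _orthogonal_pair(n=8):
    u = np.zeros(n)
    u[:2] = [1.0, -1.0]
    v = np.zeros(n)
    v[2:4] = [1.0, -1.0]
    return u, v


def _match(templates, truth):
    """Mean |correlation| of best one-to-one template assignment."""
    from scipy.optimize import linear_sum_assignment

    a = templates / np.linalg.norm(templates, axis=1, keepdims=True)
    b = truth - truth.mean(axis=1, keepdims=True)
    b = b / np.linalg.norm(b, axis=1, keepdims=True)
    corr = np.abs(a @ b.T)
    r, c = linear_sum_assignment(-corr)
    return corr[r, c].mean()


class TestModifiedKmeans:
    def test_noiseless_two_state_recovery(self):
        u, v = _orthogonal_pair()
        maps = np.array([u, v] * 20)
        res = modified_kmeans(maps, 2, polarity="respect", n_restarts=5,
                              seed=0)
        assert res.gev == pytest.approx(1.0, abs=1e-12)
        # labels must alternate consistently (up to template permutation)
        assert len(set(res.labels[::2])) == 1
        assert res.labels[0] != res.labels[1]

    def test_polarity_ignore_sign_flips_invisible(self):
        u, v = _orthogonal_pair()
        maps = np.array([u, v] * 20)
        flipped = maps.copy()
        flipped[::2] *= -1.0
        a = modified_kmeans(maps, 2, polarity="ignore", n_restarts=5, seed=3)
        b = modified_kmeans(flipped, 2, polarity="ignore", n_restarts=5,
                            seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert b.gev == pytest.approx(1.0, abs=1e-12)

    def test_q1_constant_topography(self, rng):
        u = rng.normal(size=10)
        maps = np.outer(rng.uniform(0.5, 2, 30), u)
        res = modified_kmeans(maps, 1, polarity="respect", n_restarts=3,
                              seed=1)
        t = res.templates[0]
        c = (u - u.mean())
        r = abs(t @ c) / (np.linalg.norm(t) * np.linalg.norm(c))
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_seed(self, small_sim):
        rec, _ = small_sim
        a = modified_kmeans(rec.data.T, 4, n_restarts=3, seed=42)
        b = modified_kmeans(rec.data.T, 4, n_restarts=3, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.templates, b.templates)

    def test_q_exceeding_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            modified_kmeans(rng.normal(size=(5, 8)), 6)

    def test_templates_are_unit_norm_zero_mean(self, small_sim):
        rec, _ = small_sim
        res = modified_kmeans(rec.data.T, 4, n_restarts=2, seed=0)
        np.testing.assert_allclose(
            np.linalg.norm(res.templates, axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(res.templates.mean(axis=1), 0.0,
                                   atol=1e-9)


class TestAahc:
    def test_all_singletons_explain_everything(self, rng):
        maps = rng.normal(size=(6, 8))
        results = aahc(maps, 1, 6, polarity="respect")
        top = [r for r in results if r.q == 6][0]
        assert top.gev == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_three_template_recovery(self, rng):
        truth = rng.normal(size=(3, 12))
        truth -= truth.mean(axis=1, keepdims=True)
        labels = np.repeat([0, 1, 2, 0, 1, 2], 10)
        maps = truth[labels] * rng.uniform(0.5, 2.0, size=(60, 1))
        res = [r for r in aahc(maps, 3, 3, polarity="respect")][0]
        assert _match(res.templates, truth) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_repeat_runs(self, small_sim):
        rec, _ = small_sim
        a = aahc(rec.data.T[:200], 2, 5)
        b = aahc(rec.data.T[:200], 2, 5)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.labels, rb.labels)
            np.testing.assert_array_equal(ra.templates, rb.templates)

    def test_gev_monotone_in_q(self, small_sim):
        # reassignment optimizes per-member fit, not the pooled eigen-fit,
        # so monotonicity can be violated by a hair at merge boundaries
        rec, _ = small_sim
        results = aahc(rec.data.T[:500], 1, 8)
        gevs = [r.gev for r in results]
        assert all(np.diff(gevs) >= -5e-3)

    def test_polarity_ignore_flip_invariance(self, small_sim, rng):
        rec, _ = small_sim
        maps = rec.data.T[:300].copy()
        flip = rng.random(300) < 0.5
        flipped = maps.copy()
        flipped[flip] *= -1.0
        a = [r for r in aahc(maps, 4, 4, polarity="ignore")][0]
        b = [r for r in aahc(flipped, 4, 4, polarity="ignore")][0]
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(np.abs(a.templates @ b.templates.T).max(
            axis=1), 1.0, atol=1e-9)


class TestGev:
    def test_perfect_fit_is_one(self):
        u, v = _orthogonal_pair()
        maps = np.array([u, v] * 5)
        labels = np.tile([0, 1], 5)
        assert gev(maps, labels, np.array([u, v])) == pytest.approx(
            1.0, abs=1e-12)

    def test_orthogonal_templates_zero(self):
        u, v = _orthogonal_pair()
        maps = np.array([u] * 6)
        w = np.zeros(8)
        w[4:6] = [1.0, -1.0]
        assert gev(maps, np.zeros(6, int), np.array([w])) == pytest.approx(
            0.0, abs=1e-12)

    def test_brute_force_oracle_agreement(self, rng):
        """Vectorized GEV equals explicit per-frame GFP-weighted
        squared-correlation summation."""
        from eegtopo import gfp, spatial_correlation

        maps = rng.normal(size=(40, 12))
        templates = rng.normal(size=(3, 12))
        labels = rng.integers(0, 3, size=40)
        labels[5] = UNASSIGNED
        num = den = 0.0
        for t in range(40):
            g = gfp(maps[t])
            den += g**2
            if labels[t] >= 0:
                r = spatial_correlation(maps[t], templates[labels[t]])
                num += (g * r) ** 2
        assert gev(maps, labels, templates) == pytest.approx(
            num / den, abs=1e-12)


class TestModelSelection:
    def test_perfect_fit_cv_zero(self):
        u, v = _orthogonal_pair()
        maps = np.array([u, v] * 10)
        res = modified_kmeans(maps, 2, polarity="respect", n_restarts=3,
                              seed=0)
        assert cross_validation(res, 8) == pytest.approx(0.0, abs=1e-12)

    def test_penalty_monotone_in_q(self):
        # same residual variance, increasing q -> strictly larger cv
        factor = [((19 - 1) / (19 - 1 - q)) ** 2 for q in range(1, 10)]
        assert all(np.diff(factor) > 0)

    def test_small_electrode_count_rejected(self, rng):
        maps = rng.normal(size=(20, 5))
        res = modified_kmeans(maps, 4, n_restarts=2, seed=0)
        with pytest.raises(ValueError):
            cross_validation(res, 5)

    def test_kl_needs_three_points(self):
        curve = DispersionCurve(qs=[1, 2], w=[5.0, 3.0], n_electrodes=19)
        with pytest.raises(ValueError):
            kl_criterion(curve)

    def test_kl_finds_elbow(self):
        # dispersion drops sharply until q=4, then flattens
        w = np.array([100.0, 60.0, 30.0, 5.0, 4.5, 4.0, 3.8, 3.7])
        curve = DispersionCurve(qs=np.arange(1, 9), w=w, n_electrodes=19)
        assert kl_criterion(curve) == 4

    def test_flat_profile_warns(self):
        w = np.full(6, 10.0)
        curve = DispersionCurve(qs=np.arange(1, 7), w=w, n_electrodes=19)
        with pytest.warns(UserWarning, match="corner"):
            kl_criterion(curve)


class TestSmoothing:
    def test_lambda_zero_is_identity(self, small_sim):
        rec, truth = small_sim
        res = modified_kmeans(rec.data.T, 4, n_restarts=2, seed=0)
        out = smooth_labels(res.labels, rec.data.T, res.templates,
                            penalty_lambda=0.0)
        np.testing.assert_array_equal(out, res.labels)

    def test_single_frame_label_flip_removed(self, templates4, rng):
        # all maps come from template 0; one frame is mislabeled 1
        t = templates4
        maps = np.tile(t[0], (41, 1)) + 0.1 * rng.normal(size=(41, len(t[0])))
        labels = np.array([0] * 20 + [1] + [0] * 20)
        out = smooth_labels(labels, maps, t, half_window_b=3,
                            penalty_lambda=5.0, polarity="respect")
        assert (out == 0).all()

    def test_smooth_labels_are_fixed_point(self, templates4):
        t = templates4
        labels = np.repeat([0, 1, 2, 3], 25)
        maps = t[labels]
        out = smooth_labels(labels, maps, t, half_window_b=3,
                            penalty_lambda=5.0, polarity="respect")
        np.testing.assert_array_equal(out, labels)


class TestSegmentPostprocessing:
    def test_short_run_absorbed(self):
        labels = np.array([0] * 10 + [1] + [2] * 10)
        out = reject_small_segments(labels, 3)
        runs = np.flatnonzero(np.diff(out)) + 1
        assert len(runs) == 1  # two runs remain
        assert 1 not in out

    def test_long_runs_untouched(self):
        labels = np.repeat([0, 1, 0], 10)
        np.testing.assert_array_equal(reject_small_segments(labels, 3),
                                      labels)

    def test_lonely_short_run_unassigned(self):
        labels = np.array([2, 2])
        out = reject_small_segments(labels, 5)
        assert (out == UNASSIGNED).all()

    def test_correlation_guided_absorption(self, templates4):
        t = templates4
        labels = np.array([0] * 10 + [1, 1] + [2] * 10)
        maps = t[np.array([0] * 10 + [2, 2] + [2] * 10)]
        out = reject_small_segments(labels, 3, maps=maps, templates=t,
                                    polarity="respect")
        assert (out[10:12] == 2).all()

    def test_merge_duplicate_templates(self, templates4):
        t = np.vstack([templates4[:3], templates4[2] * 1.0])
        t = t / np.linalg.norm(t, axis=1, keepdims=True)
        labels = np.repeat([0, 1, 2, 3], 10)
        maps = t[labels]
        from eegtopo.segmentation import ClusterResult

        res = ClusterResult(templates=t, labels=labels, polarity="respect",
                            gev=1.0, sigma2=0.0, cv=0.0, q=4)
        out = merge_clusters(res, 0.99, maps=maps)
        assert out.q == 3
        assert set(out.labels) == {0, 1, 2}

    def test_merge_below_threshold_identity(self, templates4):
        labels = np.repeat(np.arange(4), 5)
        from eegtopo.segmentation import ClusterResult

        t = templates4 / np.linalg.norm(templates4, axis=1, keepdims=True)
        res = ClusterResult(templates=t, labels=labels, polarity="respect",
                            gev=1.0, sigma2=0.0, cv=0.0, q=4)
        out = merge_clusters(res, 0.95)
        assert out.q == 4
        np.testing.assert_array_equal(out.labels, labels)

    def test_merge_collinear_trio_collapses(self):
        base = np.array([1.0, -1.0, 0.5, -0.5, 0.0, 0.0])
        base -= base.mean()
        base /= np.linalg.norm(base)
        t = np.vstack([base, base, -base])
        labels = np.repeat([0, 1, 2], 8)
        maps = np.vstack([base] * 8 + [base] * 8 + [-base] * 8)
        from eegtopo.segmentation import ClusterResult

        res = ClusterResult(templates=t, labels=labels, polarity="ignore",
                            gev=1.0, sigma2=0.0, cv=0.0, q=3)
        out = merge_clusters(res, 0.99, maps=maps)
        assert out.q == 1

    def test_sequentialize_splits_reoccurrence(self, templates4):
        t = templates4 / np.linalg.norm(templates4, axis=1, keepdims=True)
        labels = np.array([0] * 10 + [1] * 10 + [0] * 10)
        maps = t[labels]
        from eegtopo.segmentation import ClusterResult

        res = ClusterResult(templates=t[:2], labels=labels,
                            polarity="respect", gev=1.0, sigma2=0.0, cv=0.0,
                            q=2)
        out = sequentialize(res, maps=maps)
        assert out.q == 3
        assert len(set(out.labels[:10])) == 1
        assert out.labels[0] != out.labels[25]
        # boundaries and labeled-frame totals conserved
        assert (out.labels >= 0).sum() == (labels >= 0).sum()
        np.testing.assert_array_equal(np.flatnonzero(np.diff(out.labels)),
                                      np.flatnonzero(np.diff(labels)))


class TestLabelPermutationInvariance:
    def test_gev_unchanged_under_template_permutation(self, rng):
        maps = rng.normal(size=(30, 10))
        templates = rng.normal(size=(3, 10))
        labels = rng.integers(0, 3, 30)
        perm = np.array([2, 0, 1])  # templates[perm][inv[k]] == templates[k]
        inv = np.argsort(perm)
        g1 = gev(maps, labels, templates)
        g2 = gev(maps, inv[labels], templates[perm])
        assert g1 == pytest.approx(g2, abs=1e-12)
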