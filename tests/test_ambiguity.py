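"""Antitonic null spline and ambiguous-pair calling."""

import warnings

import numpy as np
import pytest
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from sonata.ambiguity import NullSpline, ambiguity_pvalues, fit_null_spline
from sonata.manifold import ModalityData, geodesics_from_points


def line_geodesics(n):
    """Geodesics of n evenly spaced points on a line (exact, simple)."""
    pos = np.arange(n, dtype=float)
    return np.abs(np.subtract.outer(pos, pos))


def symmetric_from_upper(n, fn, rng=None):
    """Build a symmetric consensus-like matrix from a pair function."""
    M = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    M[iu, ju] = fn(iu, ju)
    M = M + M.T
    np.fill_diagonal(M, M.max() if M.max() > 0 else 1.0)
    return M


class TestFitNullSpline:
    def test_constant_consensus_gives_constant_spline(self):
        K = line_geodesics(40)
        C = np.full((40, 40), 0.3)
        spline = fit_null_spline(C, K)
        grid = np.linspace(spline.d_min, spline.d_max, 200)
        np.testing.assert_allclose(spline(grid), 0.3, atol=1e-6)

    def test_close_to_pav_oracle_on_monotone_data(self, rng):
        K = line_geodesics(60)
        d_max = K.max()
        noise = {}

        def fn(i, j):
            d = K[i, j]
            return np.maximum(0, 1 - d / d_max) + 0.02 * rng.standard_normal(len(d))

        C = symmetric_from_upper(60, fn)
        spline = fit_null_spline(C, K)
        # oracle: pool-adjacent-violators on binned means
        iu, ju = np.triu_indices(60, 1)
        d, g = K[iu, ju], C[iu, ju]
        order = np.argsort(d)
        edges = np.linspace(0, d.size, 101).astype(int)
        centers = np.array([d[order[a:b]].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
        means = np.array([g[order[a:b]].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
        pav = IsotonicRegression(increasing=False).fit_transform(centers, means)
        assert np.abs(np.asarray(spline(centers)) - pav).max() < 0.05

    def test_increasing_signal_is_flattened(self):
        K = line_geodesics(40)
        C = symmetric_from_upper(40, lambda i, j: K[i, j] / K.max())
        spline = fit_null_spline(C, K)
        grid = np.linspace(spline.d_min, spline.d_max, 1000)
        v = np.asarray(spline(grid))
        assert (np.diff(v) <= 1e-9).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_monotone_nonincreasing_on_dense_grid(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        K, _ = geodesics_from_points(ModalityData(rng.normal(size=(n, 2))), 5)
        C = symmetric_from_upper(
            n, lambda i, j: rng.random(len(i)) * np.exp(-K.dist[i, j])
        )
        spline = fit_null_spline(C, K)
        grid = np.linspace(spline.d_min, spline.d_max, 1000)
        v = np.asarray(spline(grid))
        assert (np.diff(v) <= 1e-9).all()
        assert (v >= 0).all()

    def test_few_distances_falls_back_to_step_function(self):
        K = line_geodesics(5)  # 4 distinct distances only
        C = np.full((5, 5), 0.1)
        with pytest.warns(UserWarning, match="step-function"):
            spline = fit_null_spline(C, K)
        assert np.isfinite(spline(2.0))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_null_spline(np.ones((4, 4)), line_geodesics(5))

    def test_json_round_trip(self):
        K = line_geodesics(40)
        spline = fit_null_spline(np.full((40, 40), 0.2), K)
        back = NullSpline.from_json(spline.to_json())
        grid = np.linspace(spline.d_min, spline.d_max, 50)
        np.testing.assert_allclose(np.asarray(back(grid)), np.asarray(spline(grid)))


class TestAmbiguityPvalues:
    def _null_instance(self, seed=1, n=200):
        rng = np.random.default_rng(seed)
        K, _ = geodesics_from_points(ModalityData(rng.normal(size=(n, 3))), 15)
        Kd = K.dist
        f = 0.01 * np.exp(-Kd / (3 * np.median(Kd)))
        noise = rng.normal(size=Kd.shape) * (0.1 * f)
        noise = np.triu(noise, 1)
        g = np.maximum(f + noise + noise.T, 1e-12)
        np.fill_diagonal(g, f.max())
        return g, Kd

    def test_pvalues_uniform_under_null(self):
        """p <= alpha rate within 3 binomial SEs of alpha under the null."""
        g, Kd = self._null_instance(seed=0)
        res = ambiguity_pvalues(g, Kd)
        for alpha in (0.01, 0.05):
            rate = (res.p_value <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / res.n_pairs)
            assert abs(rate - alpha) <= 3 * se

    def test_default_cutoff_is_one_percent(self):
        g, Kd = self._null_instance()
        res = ambiguity_pvalues(g, Kd)
        assert res.alpha == 0.01

    def test_center_of_null_maps_to_half(self):
        """A residual exactly at the bin median gets p = 0.5."""
        g, Kd = self._null_instance()
        res = ambiguity_pvalues(g, Kd)
        # every equal-count bin has a pair sitting at its median
        assert (np.abs(res.p_value - 0.5) < 1e-9).any()
        assert res.p_value.min() >= 0 and res.p_value.max() <= 1

    def test_three_sigma_outlier_pvalue(self):
        """z = 3 maps to the one-sided normal tail, ~1.35e-3."""
        # single bin with an analytically controlled spread
        n = 30
        K = line_geodesics(n)
        iu, ju = np.triu_indices(n, 1)
        base = np.tile(np.array([-1.0, -0.5, 0.0, 0.5, 1.0]), iu.size // 5 + 1)[: iu.size]
        vals = 1e-4 + 1e-5 * base  # median 1e-4, MAD 0.5e-5
        mad_scale = 1.4826 * 0.5e-5
        vals[0] = 1e-4 + 3 * mad_scale  # plant a z = 3 outlier
        C = np.zeros((n, n))
        C[iu, ju] = vals
        C = C + C.T
        np.fill_diagonal(C, vals.max())
        res = ambiguity_pvalues(
            C, K, n_scale_bins=1, local_quantile=0.0, min_fold_change=1.0
        )
        p_planted = res.p_value[0]
        assert p_planted == pytest.approx(stats.norm.sf(3.0), rel=1e-6)
        assert p_planted == pytest.approx(1.35e-3, rel=0.01)
        assert res.significant[0]

    def test_zero_spread_warns_and_centers_pvalues(self):
        K = line_geodesics(30)
        C = np.full((30, 30), 0.2)
        with pytest.warns(UserWarning, match="zero spread"):
            res = ambiguity_pvalues(C, K)
        assert (res.p_value == 0.5).all()
        assert not res.significant.any()

    def test_local_pairs_never_called(self):
        g, Kd = self._null_instance()
        res = ambiguity_pvalues(g, Kd, local_quantile=0.5)
        close = res.geodesic_dist <= res.local_radius
        assert not res.significant[close].any()

    def test_invalid_local_quantile(self):
        g, Kd = self._null_instance()
        with pytest.raises(ValueError):
            ambiguity_pvalues(g, Kd, local_quantile=1.5)


class TestPlantedAmbiguity:
    def test_mirrored_branches_dominate_significant_pairs(self, small_t_pair, small_t_report):
        """>= 80% of significant pairs connect different branches."""
        res = small_t_report.result
        lab = small_t_pair.branch_labels
        sig = res.significant_pairs
        assert sig.shape[0] > 0
        cross = (lab[sig[:, 0]] != lab[sig[:, 1]]).mean()
        assert cross >= 0.8

    def test_unambiguous_path_yields_almost_no_calls(self, small_decay_pair):
        from sonata import RunConfig, diagnose

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = diagnose(small_decay_pair.modality_x, RunConfig(seed=0))
        assert rep.result.significant_fraction <= 2 * rep.result.alpha
        assert not rep.flagged_ambiguous
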