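import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stmort import geo, variogram as vg
from stmort.exceptions import ModelError, ParameterError


def brute_force_variogram(d, n_bins, cutoff, max_lag):
    """Independent pair-enumeration oracle for the empirical variogram."""
    n = len(d)
    site_coord = {}
    for i in range(n):
        site_coord[d.site_id[i]] = (d.lon[i], d.lat[i])
    sites = list(site_coord)
    dist = geo.pairwise_distance_km([site_coord[s] for s in sites])
    sidx = {s: k for k, s in enumerate(sites)}
    times = np.unique(d.t)
    dt = np.min(np.diff(times)) if len(times) > 1 else 1.0
    n_t = int(round(max_lag / dt)) + 1
    width = cutoff / n_bins
    acc = np.zeros((n_bins, n_t))
    cnt = np.zeros((n_bins, n_t), dtype=int)
    for a in range(n):
        for b in range(a + 1, n):
            h = dist[sidx[d.site_id[a]], sidx[d.site_id[b]]]
            u = abs(d.t[a] - d.t[b])
            ui = int(round(u / dt))
            if h > cutoff + 1e-12 or ui >= n_t:
                continue
            hi = min(int(h / width), n_bins - 1)
            acc[hi, ui] += (d.z[a] - d.z[b]) ** 2
            cnt[hi, ui] += 1
    gamma = np.where(cnt > 0, acc / (2.0 * np.maximum(cnt, 1)), np.nan)
    return gamma, cnt


class TestEmpiricalVariogram:
    def test_two_sites_one_time(self):
        d = vg.STDataset(np.array(["a", "b"], dtype=object),
                         [-99.0, -99.1], [19.4, 19.4], [2000.0, 2000.0],
                         [0.0, 2.0])
        ev = vg.empirical_st_variogram(d, n_spatial_bins=2, spatial_cutoff=20.0,
                                       max_temporal_lag=0.0)
        assert ev.npairs.sum() == 1
        cell = ev.gamma[ev.npairs > 0]
        assert cell[0] == pytest.approx(2.0)   # (2-0)^2 / (2*1)

    def test_constant_field_zero_gamma(self, borough_field):
        d = vg.STDataset(borough_field.site_id, borough_field.lon,
                         borough_field.lat, borough_field.t,
                         np.full(len(borough_field), 3.5))
        ev = vg.empirical_st_variogram(d)
        assert np.all(ev.gamma[ev.npairs > 0] == 0.0)

    def test_matches_brute_force_exactly(self, small_field):
        cutoff, bins, max_lag = 25.0, 4, 2.0
        ev = vg.empirical_st_variogram(small_field, n_spatial_bins=bins,
                                       spatial_cutoff=cutoff,
                                       max_temporal_lag=max_lag)
        g_ref, n_ref = brute_force_variogram(small_field, bins, cutoff, max_lag)
        assert np.array_equal(ev.npairs, n_ref)
        mask = n_ref > 0
        np.testing.assert_array_equal(ev.gamma[mask], g_ref[mask])

    def test_bad_parameters_rejected(self, small_field):
        with pytest.raises(ParameterError):
            vg.empirical_st_variogram(small_field, n_spatial_bins=1)
        with pytest.raises(ParameterError):
            vg.empirical_st_variogram(small_field, spatial_cutoff=-1.0)


class TestMarginalMeans:
    def test_two_by_two_arithmetic(self):
        ev = vg.EmpiricalSTVariogram(
            np.array([1.0, 2.0]), np.array([0.0, 1.0]),
            np.array([[1.0, 3.0], [2.0, 4.0]]), np.ones((2, 2), dtype=int))
        assert vg.marginal_means(ev, "spatial") == pytest.approx([2.0, 3.0])
        assert vg.marginal_means(ev, "temporal") == pytest.approx([1.5, 3.5])

    def test_random_matrix_resummation_oracle(self):
        rng = np.random.default_rng(8)
        gamma = rng.uniform(0, 5, (8, 17))
        npairs = rng.integers(0, 4, (8, 17))
        ev = vg.EmpiricalSTVariogram(np.arange(1, 9.0), np.arange(17.0),
                                     gamma, npairs)
        got_s = vg.marginal_means(ev, "spatial")
        for i in range(8):
            vals = [gamma[i, j] for j in range(17) if npairs[i, j] > 0]
            if vals:
                assert got_s[i] == pytest.approx(sum(vals) / len(vals))
            else:
                assert np.isnan(got_s[i])


class TestInitialGuess:
    def _ev_with_row_means(self, row_vals, bin_max=30.0, n_lags=17):
        n = len(row_vals)
        gamma = np.tile(np.asarray(row_vals, float)[:, None], (1, n_lags))
        centers = np.linspace(bin_max / n, bin_max, n) - bin_max / (2 * n)
        centers = centers + bin_max / (2 * n)  # bin centers ending at bin_max
        return vg.EmpiricalSTVariogram(centers, np.arange(n_lags, dtype=float),
                                       gamma, np.ones((n, n_lags), dtype=int))

    def test_median_rules(self):
        ev = self._ev_with_row_means(np.arange(1.0, 11.0))
        ig = vg.initial_guess(ev)
        assert ig.nugget_s == pytest.approx(2.0)   # median of (1,2,3)
        assert ig.sill_s == pytest.approx(8.0)     # median of (6..10)

    def test_range_rules(self):
        ev = self._ev_with_row_means(np.arange(1.0, 11.0), bin_max=30.0,
                                     n_lags=17)
        ig = vg.initial_guess(ev)
        assert ig.range_s == pytest.approx(30.0 / 3.0)
        assert ig.range_t == pytest.approx(16.0)

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(9)
        gamma = np.abs(rng.normal(2.0, 1.0, (10, 10)))
        npairs = np.ones((10, 10), dtype=int)
        centers = np.linspace(1.0, 28.0, 10)
        lags = np.arange(10.0)
        ev = vg.EmpiricalSTVariogram(centers, lags, gamma, npairs)
        ig = vg.initial_guess(ev)
        # hand-coded oracle for the bullet rules
        mm_s = gamma.mean(axis=1)
        mm_t = gamma.mean(axis=0)
        assert ig.nugget_s == pytest.approx(np.median(mm_s[:3]))
        assert ig.nugget_t == pytest.approx(np.median(mm_t[:3]))
        assert ig.sill_s == pytest.approx(np.median(mm_s[-5:]))
        assert ig.sill_t == pytest.approx(np.median(mm_t[-5:]))
        assert ig.range_s == pytest.approx(centers.max() / 3.0)
        assert ig.range_t == pytest.approx(lags.max())
        st_ani = vg.estimate_stani(ev)
        assert ig.stAni == pytest.approx(st_ani)
        assert ig.nugget_j == pytest.approx((ig.nugget_s + ig.nugget_t) / 2)
        assert ig.sill_j == pytest.approx((ig.sill_s + ig.sill_t) / 2)
        assert ig.range_j == pytest.approx(
            (ig.range_s + st_ani * ig.range_t) / 2)


class TestEstimateStani:
    def _ev(self, gamma):
        n, m = gamma.shape
        return vg.EmpiricalSTVariogram(np.arange(1.0, n + 1),
                                       np.arange(float(m)), gamma,
                                       np.ones((n, m), dtype=int))

    def test_exact_linear_margins(self):
        h = np.arange(1.0, 7.0)
        u = np.arange(6.0)
        gamma = np.zeros((6, 6))
        gamma[:, 0] = 2.0 * h           # purely spatial margin
        gamma[0, :] = 6.0 * u           # purely temporal margin
        npairs = np.ones((6, 6), dtype=int)
        npairs[0, 0] = 0                # origin cell has no pairs
        ev = vg.EmpiricalSTVariogram(h, u, gamma, npairs)
        assert vg.estimate_stani(ev) == pytest.approx(3.0, rel=1e-9)

    def test_identical_margins_unity(self):
        gamma = np.zeros((5, 5))
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        gamma[:, 0] = vals
        gamma[0, :] = vals
        ev = vg.EmpiricalSTVariogram(np.arange(1.0, 6.0), np.arange(1.0, 6.0),
                                     gamma, np.ones((5, 5), dtype=int))
        assert vg.estimate_stani(ev) == pytest.approx(1.0)

    def test_noisy_margins_match_normal_equations(self):
        rng = np.random.default_rng(10)
        h = np.arange(1.0, 11.0)
        u = np.arange(10.0)
        gs = 0.5 + 2.0 * h + rng.normal(0, 0.1, 10)
        gt = 0.2 + 5.0 * u + rng.normal(0, 0.1, 10)
        gamma = np.ones((10, 10))
        gamma[:, 0] = gs
        gamma[0, :] = gt
        npairs = np.ones((10, 10), dtype=int)
        npairs[0, 0] = 0
        ev = vg.EmpiricalSTVariogram(h, u, gamma, npairs)

        def ls_slope(x, y):
            A = np.column_stack([np.ones_like(x), x])
            return np.linalg.solve(A.T @ A, A.T @ y)[1]

        expected = ls_slope(u[1:], gt[1:]) / ls_slope(h[1:], gs[1:])
        assert vg.estimate_stani(ev) == pytest.approx(expected, abs=1e-10)


class TestEvalComponent:
    def test_spherical_values(self):
        c = vg.VariogramComponent("Sph", 0.0, 1.0, 2.0)
        assert vg.eval_component(c, 2.0) == pytest.approx(1.0)
        assert vg.eval_component(c, 1.0) == pytest.approx(0.6875)

    def test_exponential_efolding(self):
        c = vg.VariogramComponent("Exp", 0.0, 1.0, 3.0)
        assert vg.eval_component(c, 3.0) == pytest.approx(1 - math.exp(-1))

    def test_gaussian_sill_limit(self):
        c = vg.VariogramComponent("Gau", 0.2, 0.8, 1.5)
        assert vg.eval_component(c, 15.0) == pytest.approx(1.0, abs=1e-12)

    def test_negative_lag_rejected(self):
        c = vg.VariogramComponent("Exp", 0.0, 1.0, 1.0)
        with pytest.raises(ParameterError):
            vg.eval_component(c, -0.1)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(family=st.sampled_from(vg.FAMILIES),
           nugget=st.floats(0, 5), psill=st.floats(0, 5),
           range_=st.floats(0.01, 50))
    def test_zero_origin_and_monotone(self, family, nugget, psill, range_):
        c = vg.VariogramComponent(family, nugget, psill, range_)
        assert vg.eval_component(c, 0.0) == 0.0
        h = np.linspace(1e-9, 5 * range_, 200)
        g = vg.eval_component(c, h)
        assert np.all(np.diff(g) >= -1e-12)
        assert np.all(g >= 0)


def _models(ig=None):
    ig = ig or vg.InitialGuess(0.2, 0.3, 1.5, 1.2, 8.0, 12.0, 0.8,
                               0.25, 1.35, 8.8)
    return [vg.make_initial_model(s, f, ig) for s, f in [
        ("metric", ("Gau",)), ("separable", ("Exp", "Sph")),
        ("productSum", ("Sph", "Gau")), ("sumMetric", ("Gau", "Exp", "Sph")),
        ("simpleSumMetric", ("Exp", "Exp", "Gau"))]]


class TestEvalStModel:
    @pytest.mark.parametrize("model", _models(), ids=lambda m: m.structure)
    def test_zero_at_origin(self, model):
        assert vg.eval_st_model(model, 0.0, 0.0) == 0.0

    def test_separable_pure_spatial_margin(self):
        m = _models()[1]
        for h in (0.5, 3.0, 20.0):
            expected = m.sill * (vg.eval_component(m.space, h) / m.space.sill)
            assert vg.eval_st_model(m, h, 0.0) == pytest.approx(expected)

    def test_summetric_term_by_term_oracle(self):
        m = _models()[3]
        rng = np.random.default_rng(12)
        for h, u in rng.uniform(0.1, 20, (20, 2)):
            hm = math.hypot(h, m.stAni * u)
            expected = (vg.eval_component(m.space, h)
                        + vg.eval_component(m.time, u)
                        + vg.eval_component(m.joint, hm))
            assert vg.eval_st_model(m, h, u) == pytest.approx(expected, rel=1e-12)

    def test_structure_component_mismatch_rejected(self):
        with pytest.raises(ModelError):
            vg.STCovModel("metric", space=vg.VariogramComponent("Gau", 0, 1, 1),
                          joint=vg.VariogramComponent("Gau", 0, 1, 1), stAni=1.0)
        with pytest.raises(ModelError):
            vg.STCovModel("separable", space=vg.VariogramComponent("Gau", 0, 1, 1))


def _ev_from_model(model, centers, lags):
    H, U = np.meshgrid(centers, lags, indexing="ij")
    gamma = vg.eval_st_model(model, H, U)
    return vg.EmpiricalSTVariogram(centers, lags, gamma,
                                   np.ones(gamma.shape, dtype=int))


class TestFit:
    def test_metric_gau_inverse_crime(self):
        truth = vg.STCovModel("metric", joint=vg.VariogramComponent(
            "Gau", 0.1, 1.2, 9.0), stAni=1.5)
        ev = _ev_from_model(truth, np.linspace(1, 30, 12), np.arange(13.0))
        init = vg.STCovModel("metric", joint=vg.VariogramComponent(
            "Gau", 0.3, 0.8, 5.0), stAni=0.8)
        fit = vg.fit_st_model(ev, init)
        assert fit.wmse < 1e-10
        assert fit.model.joint.nugget == pytest.approx(0.1, abs=1e-4)
        assert fit.model.joint.psill == pytest.approx(1.2, abs=1e-4)
        assert fit.model.joint.range_ == pytest.approx(9.0, abs=1e-3)

    def test_already_optimal_is_fixed_point(self):
        truth = vg.STCovModel("metric", joint=vg.VariogramComponent(
            "Exp", 0.1, 1.0, 6.0), stAni=1.0)
        ev = _ev_from_model(truth, np.linspace(1, 30, 10), np.arange(8.0))
        fit = vg.fit_st_model(ev, truth)
        assert fit.wmse < 1e-12

    def test_weight_scheme_changes_objective(self):
        truth = vg.STCovModel("metric", joint=vg.VariogramComponent(
            "Sph", 0.2, 1.0, 10.0), stAni=1.0)
        centers, lags = np.linspace(1, 30, 10), np.arange(8.0)
        H, U = np.meshgrid(centers, lags, indexing="ij")
        rng = np.random.default_rng(13)
        gamma = vg.eval_st_model(truth, H, U) + rng.normal(0, 0.15, H.shape)
        gamma = np.abs(gamma)
        npairs = rng.integers(1, 60, H.shape)
        ev = vg.EmpiricalSTVariogram(centers, lags, gamma, npairs)
        f_np = vg.fit_st_model(ev, truth, weights="npairs")
        f_eq = vg.fit_st_model(ev, truth, weights="equal")
        assert f_np.wmse >= 0 and f_eq.wmse >= 0
        # direct wMSE re-evaluation oracle
        assert f_np.wmse == pytest.approx(
            vg.weighted_mse(f_np.model, ev, "npairs"), rel=1e-10)
        assert f_eq.wmse == pytest.approx(
            vg.weighted_mse(f_eq.model, ev, "equal"), rel=1e-10)
        assert f_np.model.to_dict() != f_eq.model.to_dict()

    def test_box_constraint_respected(self):
        truth = vg.STCovModel("metric", joint=vg.VariogramComponent(
            "Gau", 0.0, 1.0, 5.0), stAni=1.0)
        ev = _ev_from_model(truth, np.linspace(1, 30, 10), np.arange(8.0))
        init = vg.STCovModel("metric", joint=vg.VariogramComponent(
            "Gau", 0.5, 1.0, 5.0), stAni=1.0)
        fit = vg.fit_st_model(ev, init)
        m = fit.model
        assert m.joint.nugget >= vg.LOWER_BOUND
        assert m.joint.psill >= vg.LOWER_BOUND
        assert m.joint.range_ >= vg.LOWER_BOUND
        assert m.stAni >= vg.LOWER_BOUND


class TestGridSearch:
    def test_candidate_combinatorics(self):
        ig = vg.InitialGuess(0.2, 0.3, 1.5, 1.2, 8.0, 12.0, 0.8,
                             0.25, 1.35, 8.8)
        cands = vg.candidate_models(ig)
        assert len(cands) == 75
        counts = {}
        for c in cands:
            counts[c.structure] = counts.get(c.structure, 0) + 1
        assert counts == {"metric": 3, "separable": 9, "productSum": 9,
                          "sumMetric": 27, "simpleSumMetric": 27}

    def test_search_is_permutation_and_sorted(self):
        truth = vg.STCovModel("sumMetric",
                              space=vg.VariogramComponent("Gau", 0.05, 0.6, 7.0),
                              time=vg.VariogramComponent("Gau", 0.05, 0.5, 6.0),
                              joint=vg.VariogramComponent("Gau", 0.02, 0.3, 8.0),
                              stAni=1.2)
        ev = _ev_from_model(truth, np.linspace(1.5, 28, 10), np.arange(9.0))
        ig = vg.initial_guess(ev)
        fits = vg.grid_search(ev, ig)
        assert len(fits) == 75
        keys = sorted((f.model.structure, f.model.families()) for f in fits)
        expected = sorted((c.structure, c.families())
                          for c in vg.candidate_models(ig))
        assert keys == expected
        wmses = [f.wmse for f in fits]
        assert wmses == sorted(wmses)
        # data generated from sumMetric: winner beats every metric candidate
        best_metric = min(f.wmse for f in fits if f.model.structure == "metric")
        assert fits[0].wmse <= best_metric
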