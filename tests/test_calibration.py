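import numpy as np
import pytest

import brainpv as bp
from brainpv import calibration as cal
from brainpv.calibration import (
    HIST_RANGES,
    N_BINS,
    RidgeSet,
    build_histograms,
    chi2_threshold,
    confidence_interval,
    cost,
    extract_ridge,
    manifold_compositions,
)


def _qmaps_from_points(points):
    """Wrap a (N, 3) set of (R1, R2, PD) triples as a 1-D QMaps volume."""
    pts = np.asarray(points, dtype=float)
    shape = (len(pts), 1, 1)
    return bp.QMaps(
        r1=pts[:, 0].reshape(shape), r2=pts[:, 1].reshape(shape),
        pd=pts[:, 2].reshape(shape), a=np.ones(shape),
        mask=np.ones(shape, dtype=bool),
    )


class TestHistograms:
    def test_single_voxel_lands_in_one_bin_per_grid(self):
        h = build_histograms(_qmaps_from_points([[1.0, 10.0, 75.0]]))
        for grid in (h.h_r1r2, h.h_r1pd, h.h_r2pd):
            assert grid.sum() == 1
            assert grid.max() == 1

    def test_out_of_range_voxel_excluded_everywhere(self):
        h = build_histograms(_qmaps_from_points([[1.0, 20.0, 75.0]]))
        assert h.h_r1r2.sum() == 0 and h.h_r1pd.sum() == 0 and h.h_r2pd.sum() == 0

    def test_totals_equal_voxel_count(self):
        rng = np.random.default_rng(3)
        pts = np.stack([rng.uniform(0.1, 1.9, 50), rng.uniform(1, 14, 50),
                        rng.uniform(55, 95, 50)], axis=1)
        h = build_histograms(_qmaps_from_points(pts))
        assert h.h_r1r2.sum() == h.h_r1pd.sum() == h.h_r2pd.sum() == 50

    def test_empty_mask_rejected(self):
        qm = _qmaps_from_points([[1.0, 10.0, 75.0]])
        with pytest.raises(ValueError, match="empty mask"):
            build_histograms(qm, mask=np.zeros_like(qm.mask))


class TestRidge:
    def test_ridge_follows_constructed_curve(self):
        rng = np.random.default_rng(4)
        r1 = rng.uniform(0.2, 1.8, 20000)
        r2 = np.clip(5 * r1 + rng.normal(0, 0.1, r1.size), 0.01, 14.99)
        pd = np.clip(100 - 20 * r1 + rng.normal(0, 0.3, r1.size), 51, 99)
        ridge = extract_ridge(build_histograms(_qmaps_from_points(
            np.stack([r1, r2, pd], axis=1))), min_count=5)
        sel = ridge.axis == 0
        bin_w = (HIST_RANGES[1][1] - HIST_RANGES[1][0]) / N_BINS
        close = np.abs(ridge.r2[sel] - 5 * ridge.r1[sel]) <= (0.1 + bin_w)
        assert close.mean() >= 0.95

    def test_sparse_columns_yield_exactly_their_triples(self):
        # two well-separated 5-voxel clusters: each populated column must
        # return exactly the cluster's own values (to bin-center rounding)
        a, b = [0.505, 2.2875, 60.125], [1.505, 12.2625, 90.125]
        ridge = extract_ridge(build_histograms(_qmaps_from_points(
            [a] * 5 + [b] * 5)), min_count=5)
        sel = ridge.axis == 0
        assert sel.sum() == 2
        got = sorted(zip(ridge.r1[sel], ridge.r2[sel], ridge.pd[sel]))
        np.testing.assert_allclose(got[0], a, atol=0.13)
        np.testing.assert_allclose(got[1], b, atol=0.13)

    def test_tie_breaks_toward_lower_bin(self):
        h = np.zeros((N_BINS, N_BINS))
        h[10, 20] = 5
        h[10, 40] = 5  # equal maxima in column 10
        h[50, 60] = 7  # second cluster keeps ridge variances positive
        hset = cal.Histogram2DSet(h_r1r2=h, h_r1pd=h, h_r2pd=h)
        ridge = extract_ridge(hset, min_count=5)
        lo0, hi0 = HIST_RANGES[0]
        r1_col10 = lo0 + (10 + 0.5) * (hi0 - lo0) / N_BINS
        sel = (ridge.axis == 0) & np.isclose(ridge.r1, r1_col10)
        lo1, hi1 = HIST_RANGES[1]
        expected = lo1 + (20 + 0.5) * (hi1 - lo1) / N_BINS
        assert np.isclose(ridge.r2[sel][0], expected)

    def test_empty_histograms_rejected(self):
        h = np.zeros((N_BINS, N_BINS))
        hset = cal.Histogram2DSet(h_r1r2=h, h_r1pd=h, h_r2pd=h)
        with pytest.raises(ValueError):
            extract_ridge(hset)


class TestManifold:
    def test_composition_count_and_caps(self):
        comps = manifold_compositions()
        assert comps.shape == (141, 4)
        assert np.all(comps[:, 0] <= 0.40 + 1e-12)
        np.testing.assert_allclose(comps.sum(axis=1), 1.0)

    def test_fixed_water_endpoint(self, manifold_points):
        np.testing.assert_allclose(manifold_points[100], [0.24, 0.87, 100.0],
                                   atol=5e-3)

    def test_pure_cellular_point_shares_fit_path(self, model, hard_seq, manifold_points):
        sig = bp.simulate_sequence(bp.VoxelComposition(0, 1.0, 0, 0), model, hard_seq)
        from brainpv.qmapfit import fit_signal_batch

        fit = fit_signal_batch(sig, hard_seq, fit_b1=True)
        assert np.isclose(manifold_points[0, 0], fit["r1"][0], atol=1e-9)
        assert np.isclose(manifold_points[0, 1], fit["r2"][0], atol=1e-9)

    def test_myelin_branch_monotone_in_r1(self, manifold_points):
        branch = manifold_points[101:]
        assert np.all(np.diff(branch[:, 0]) > 0)


class TestCost:
    def _ridge_from_points(self, pts, axis=None):
        pts = np.asarray(pts, dtype=float)
        ax = np.zeros(len(pts), dtype=int) if axis is None else np.asarray(axis)
        sig2 = tuple(np.maximum(np.var(pts[:, k]), 1e-6) for k in range(3))
        return RidgeSet(r1=pts[:, 0], r2=pts[:, 1], pd=pts[:, 2], axis=ax, sigma2=sig2)

    def test_identical_points_zero_cost(self, manifold_points):
        ridge = self._ridge_from_points(manifold_points,
                                        axis=np.arange(141) % 3)
        assert cost(manifold_points, ridge) == pytest.approx(0.0, abs=1e-20)

    def test_unit_residual_contributes_one_over_n(self):
        # three well-separated R1-indexed ridge points with unit variances;
        # shifting one model point by sqrt(sigma2_R2) in R2 puts exactly one
        # unit residual into one term of the grouped cost
        base = np.array([[0.5, 2.0, 60.0], [1.0, 8.0, 80.0], [1.5, 14.0, 95.0]])
        ridge = RidgeSet(r1=base[:, 0], r2=base[:, 1], pd=base[:, 2],
                         axis=np.zeros(3, int), sigma2=(1.0, 1.0, 1.0))
        pts = base.copy()
        pts[1, 1] += 1.0
        assert cost(pts, ridge) == pytest.approx(1.0 / 3.0, rel=1e-9)

    def test_invariant_under_joint_axis_rescaling(self, manifold_points):
        ridge = self._ridge_from_points(manifold_points)
        c0 = cost(manifold_points * [2.0, 1.0, 1.0] + [0.1, 0, 0], ridge)
        scaled = self._ridge_from_points(manifold_points * [3.0, 1.0, 1.0])
        scaled = RidgeSet(r1=scaled.r1, r2=scaled.r2, pd=scaled.pd, axis=scaled.axis,
                          sigma2=(ridge.sigma2[0] * 9.0, ridge.sigma2[1], ridge.sigma2[2]))
        c1 = cost(manifold_points * [2.0, 1.0, 1.0] * [3.0, 1, 1] + [0.3, 0, 0], scaled)
        assert c1 == pytest.approx(c0, rel=1e-9)

    def test_zero_variance_rejected(self, manifold_points):
        with pytest.raises(ValueError):
            RidgeSet(r1=manifold_points[:, 0], r2=manifold_points[:, 1],
                     pd=manifold_points[:, 2], axis=np.zeros(141, int),
                     sigma2=(0.0, 1.0, 1.0))


class TestChi2:
    def test_default_ci_bound_is_printed_value(self):
        assert cal.default_ci_threshold() == pytest.approx(9.488, abs=5e-4)

    def test_single_dof_quantile(self):
        assert chi2_threshold(0.05, 1) == pytest.approx(3.841, abs=5e-4)

    def test_monotone_in_dof(self):
        vals = [chi2_threshold(0.05, df) for df in range(1, 8)]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            chi2_threshold(1.5, 5)
        with pytest.raises(ValueError):
            chi2_threshold(0.05, 0)


@pytest.fixture(scope="module")
def synthetic_ridge(manifold_points):
    """Ridge sitting exactly on the forward-model manifold."""
    ax = np.arange(141) % 3
    sig2 = tuple(float(np.var(manifold_points[:, k])) for k in range(3))
    return RidgeSet(r1=manifold_points[:, 0], r2=manifold_points[:, 1],
                    pd=manifold_points[:, 2], axis=ax, sigma2=sig2)


class TestOptimizer:
    def test_single_restart_is_reproducible(self, synthetic_ridge, hard_seq):
        a = bp.optimize(synthetic_ridge, hard_seq, n_restarts=1, seed=123)
        b = bp.optimize(synthetic_ridge, hard_seq, n_restarts=1, seed=123)
        assert a.theta == b.theta
        assert a.min_cost == b.min_cost

    def test_result_respects_ordering_constraints(self, synthetic_ridge, hard_seq):
        res = bp.optimize(synthetic_ridge, hard_seq, n_restarts=2, seed=5)
        m = res.model
        assert m.fw.r1 < m.cl.r1 < m.my.r1
        assert m.fw.r2 < m.cl.r2 < m.my.r2

    def test_infeasible_assembly_returns_none(self, model):
        theta = dict(r1_my=0.5, pd_my=42.0, k_my_cl=6.7, r1_cl=0.78,
                     r2_cl=10.3, pd_cl=85.0)  # r1_my < r1_cl
        assert cal._assemble(theta, model) is None


class TestAnatomicalCohortCalibration:
    def test_shallow_minimum_with_tissue_cohort(self, model, hard_seq, a_scale):
        """Calibrating against an anatomical phantom, whose most
        cellular-like tissue still carries ~2% myelin, constrains the
        cellular compartment only loosely: the pure-CL knee is fixed by
        extrapolation, so R1_CL lands within tens of percent while R2_CL
        and PD_CL stay within ~10%.  This mirrors the wide calibrated
        uncertainty of the in vivo procedure."""
        ph = bp.make_phantom(bp.PhantomSpec())
        series = bp.simulate_acquisition(ph, model, hard_seq, noise_sigma_pct=0.0)
        qm = bp.fit_volume(series, hard_seq, ph.icv_mask, fit_b1=True,
                           a_scale=a_scale, voxel_size_mm=(ph.spec.voxel_mm,) * 3)
        ridge = extract_ridge(build_histograms(qm), min_count=5)
        res = bp.optimize(ridge, hard_seq, n_restarts=3, seed=11)
        assert abs(res.theta["r1_cl"] - 0.78) / 0.78 < 0.25
        assert abs(res.theta["r2_cl"] - 10.3) / 10.3 < 0.10
        assert abs(res.theta["pd_cl"] - 85.0) / 85.0 < 0.06


class TestConfidenceInterval:
    def _result(self, x0=1.0):
        theta = dict(r1_my=16.6, pd_my=42.0, k_my_cl=6.7, r1_cl=x0,
                     r2_cl=10.3, pd_cl=85.0)
        m = cal._assemble(theta, bp.default_model_params())
        return cal.CalibrationResult(model=m, min_cost=0.0, theta=theta)

    def test_quadratic_cost_gives_closed_form_interval(self):
        s = 0.004
        res = self._result(x0=1.0)
        fn = lambda th: (th["r1_cl"] - 1.0) ** 2 / s
        lo, hi, open_ended = confidence_interval(res, ridge=None, param_name="r1_cl",
                                                 cost_fn=fn, n_scan=400)
        half = np.sqrt(9.488 * s)
        assert lo == pytest.approx(1.0 - half, abs=2e-3)
        assert hi == pytest.approx(1.0 + half, abs=2e-3)
        assert open_ended == (False, False)

    def test_flat_direction_flagged_open(self):
        res = self._result()
        lo, hi, open_ended = confidence_interval(res, ridge=None, param_name="r1_cl",
                                                 cost_fn=lambda th: 0.0, n_scan=10)
        assert open_ended == (True, True)
        assert lo == pytest.approx(cal.PARAM_RANGES["r1_cl"][0])

    def test_interval_contains_optimum(self):
        res = self._result(x0=0.9)
        fn = lambda th: 10 * (th["r1_cl"] - 0.9) ** 2
        lo, hi, _ = confidence_interval(res, ridge=None, param_name="r1_cl",
                                        cost_fn=fn, n_scan=50)
        assert lo <= 0.9 <= hi

    def test_cost_above_threshold_rejected(self):
        res = self._result()
        res.min_cost = 100.0
        with pytest.raises(ValueError):
            confidence_interval(res, ridge=None, param_name="r1_cl",
                                cost_fn=lambda th: 100.0)
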