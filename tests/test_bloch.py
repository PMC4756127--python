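import numpy as np
import pytest

import brainpv as bp
from brainpv.bloch import (
    exchange_step_matrices,
    gradient_rotation,
    relaxation_exchange_step,
    rf_rotation,
    simulate_batch,
)
from brainpv.params import VoxelComposition
from brainpv.qmapfit import fit_signal_batch
from brainpv.sequence import GAMMA_HZ_PER_T


class TestRotations:
    @pytest.mark.parametrize("flip,axis,start,expect", [
        (180.0, "x", (0, 0, 1), (0, 0, -1)),
        (90.0, "x", (0, 0, 1), (0, -1, 0)),
        (90.0, "y", (0, 0, 1), (1, 0, 0)),
    ])
    def test_known_rotations(self, flip, axis, start, expect):
        out = rf_rotation(flip, axis, np.array(start, dtype=float))
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_two_quarter_turns_compose_to_half_turn(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=3)
        twice = rf_rotation(90.0, "x", rf_rotation(90.0, "x", v))
        once = rf_rotation(180.0, "x", v)
        assert np.max(np.abs(twice - once)) < 1e-12

    def test_norm_preserved(self):
        v = np.array([0.3, -0.5, 0.8])
        out = rf_rotation(37.0, "y", v)
        assert np.isclose(np.linalg.norm(out), np.linalg.norm(v))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rf_rotation(90.0, "x", np.array([np.nan, 0, 0]))
        with pytest.raises(ValueError):
            rf_rotation(90.0, "z", np.array([1.0, 0, 0]))


class TestGradientRotation:
    def test_isocenter_unchanged(self):
        v = np.array([0.5, 0.2, 0.8])
        np.testing.assert_allclose(gradient_rotation(1e-3, 0.0, 1e-6, v), v)

    def test_pi_rotation_flips_transverse(self):
        # choose G, d, t such that 2*pi*gamma*G*d*t = pi
        d, dt = 1e-3, 1e-6
        g = 0.5 / (GAMMA_HZ_PER_T * d * dt)
        out = gradient_rotation(g, d, dt, np.array([1.0, 0, 0]))
        np.testing.assert_allclose(out, [-1.0, 0, 0], atol=1e-9)

    def test_spoiler_dephases_uniform_transverse(self):
        # cell-centered elements with a 4*pi total spread: the transverse
        # phases are n-th roots of unity and sum to zero analytically
        n = 150
        d = (np.arange(n) + 0.5 - n / 2) * 1e-4  # meters
        dt = 1e-3
        spread = 4 * np.pi
        g = spread / (2 * np.pi * GAMMA_HZ_PER_T * n * 1e-4 * dt)
        total = np.zeros(3)
        for di in d:
            total += gradient_rotation(g, di, dt, np.array([1.0, 0.0, 0.0]))
        assert np.abs(total[0] + 1j * total[1]) / n < 1e-3
        assert total[2] == 0.0


class TestRelaxationExchangeStep:
    def test_decoupled_limit_is_monoexponential(self, model):
        m = model.replace(k_my_cl=0.0)
        comp = VoxelComposition(0.2, 0.8, 0.0, 0.0)
        dt = 1e-4
        mz = np.array([0.1, -0.3, 0.7, 0.2])
        mxy = np.array([0.5, 0.4, 0.3, 0.2])
        mz2, mxy2 = relaxation_exchange_step(mz, mxy, comp, m, dt)
        r1 = np.array([c.r1 for c in m.compartments])
        r2 = np.array([c.r2 for c in m.compartments])
        e1, e2 = np.exp(-dt * r1), np.exp(-dt * r2)
        np.testing.assert_allclose(mz2, e1 * mz + (1 - e1), atol=1e-12)
        np.testing.assert_allclose(mxy2, e2 * mxy, atol=1e-12)

    def test_equilibrium_is_fixed_point(self, model):
        comp = VoxelComposition(0.1, 0.6, 0.1, 0.2)
        mz2, mxy2 = relaxation_exchange_step(np.ones(4), np.zeros(4), comp, model, 1e-6)
        np.testing.assert_allclose(mz2, np.ones(4), atol=1e-12)
        np.testing.assert_allclose(mxy2, np.zeros(4), atol=1e-12)

    def test_exchange_conserves_pd_weighted_magnetization(self, model):
        # the coupling part of the update (relaxation removed) must leave
        # the PD-weighted longitudinal sum invariant: w @ X == 0
        comps = np.array([[0.2, 0.5, 0.1, 0.2], [0.3, 0.7, 0.0, 0.0]])
        a_l, _, a_t = exchange_step_matrices(model, comps, 1e-6)
        pd = np.array([c.pd for c in model.compartments])
        w = comps * pd
        for a, rates in ((a_l, [c.r1 for c in model.compartments]),
                         (a_t, [c.r2 for c in model.compartments])):
            x = a - np.diag(np.exp(-1e-6 * np.array(rates)))[None]
            np.testing.assert_allclose(np.einsum("bi,bij->bj", w, x), 0.0, atol=1e-12)

    def test_degenerate_pair_weights_give_zero_coupling(self, model):
        # no cellular partner: myelin and excess water must relax alone
        comps = np.array([[0.5, 0.0, 0.0, 0.5]])
        a_l, _, _ = exchange_step_matrices(model, comps, 1e-6)
        off_diag = a_l[0] - np.diag(np.diag(a_l[0]))
        np.testing.assert_allclose(off_diag, 0.0, atol=1e-15)

    def test_coarse_step_warns(self, model):
        comp = VoxelComposition(0.0, 1.0, 0.0, 0.0)
        with pytest.warns(UserWarning, match="dt too coarse"):
            relaxation_exchange_step(np.ones(4), np.zeros(4), comp, model, 1e-3)


class TestSimulateSequence:
    def test_pure_free_water_recovery_rate(self, model, hard_seq):
        sig = bp.simulate_sequence(VoxelComposition(0, 0, 1.0, 0), model, hard_seq)
        fit = fit_signal_batch(sig, hard_seq, fit_b1=True)
        assert abs(fit["r1"][0] - 0.24) < 0.01

    def test_empty_voxel_gives_zero_signal(self, model, hard_seq):
        sig, _ = simulate_batch(np.zeros((1, 4)), model, hard_seq)
        assert np.all(sig == 0.0)

    def test_slice_profile_pure_cl_self_consistency(self, model, shaped_seq):
        """Full slice-profile simulation of a pure-cellular voxel fits
        back to its generating relaxation rates."""
        sig, conv = simulate_batch(np.array([[0, 1.0, 0, 0]]), model, shaped_seq)
        assert conv[0]
        fit = fit_signal_batch(sig, shaped_seq, fit_b1=True)
        assert abs(fit["r1"][0] - 0.78) < 0.05
        assert abs(fit["r2"][0] - 10.3) < 0.05

    def test_fitted_rates_increase_with_myelin(self, model, hard_seq):
        v_my = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        comps = np.stack([v_my, 1 - v_my, 0 * v_my, 0 * v_my], axis=1)
        sig, _ = simulate_batch(comps, model, hard_seq)
        fit = fit_signal_batch(sig, hard_seq, fit_b1=True)
        assert np.all(np.diff(fit["r1"]) > 0)
        assert np.all(np.diff(fit["r2"]) > 0)
        pd = fit["m0"]
        assert np.all(np.diff(pd) < 0)

    def test_exchange_pulls_rates_toward_myelin(self, model, hard_seq):
        rates_r1, rates_r2 = [], []
        for k in (0.0, 2.0, 6.7, 20.0):
            m = model.replace(k_my_cl=k)
            sig, _ = simulate_batch(np.array([[0.2, 0.8, 0, 0]]), m, hard_seq)
            fit = fit_signal_batch(sig, hard_seq, fit_b1=True)
            rates_r1.append(fit["r1"][0])
            rates_r2.append(fit["r2"][0])
        assert np.all(np.diff(rates_r1) > 0)
        assert np.all(np.diff(rates_r2) > 0)

    def test_free_and_excess_water_curves_are_distinct(self, model, hard_seq):
        """The CSF-mixing curve and the edema-dilution curve must separate
        in (R1, R2) at matched PD, else the inversion could not tell bulk
        CSF from parenchymal excess water."""
        frac = np.linspace(0.0, 0.9, 10)
        fw_comps = np.stack([0 * frac, 1 - frac, frac, 0 * frac], axis=1)
        epw_comps = np.stack([0 * frac, 1 - frac, 0 * frac, frac], axis=1)
        sig, _ = simulate_batch(np.vstack([fw_comps, epw_comps]), model, hard_seq)
        fit = fit_signal_batch(sig, hard_seq, fit_b1=True)
        n = len(frac)
        fw = np.stack([fit["r1"][:n], fit["r2"][:n], fit["m0"][:n]], axis=1)
        ep = np.stack([fit["r1"][n:], fit["r2"][n:], fit["m0"][n:]], axis=1)
        sigma = np.std(np.vstack([fw, ep]), axis=0)
        # match points of equal PD by interpolating the FW curve
        sep = []
        for row in ep:
            j = np.argmin(np.abs(fw[:, 2] - row[2]))
            sep.append(np.hypot((row[0] - fw[j, 0]) / sigma[0],
                                (row[1] - fw[j, 1]) / sigma[1]))
        assert max(sep) > 0.5

    def test_signal_matrix_validation_and_export(self, model, hard_seq, tmp_path):
        sig = bp.simulate_sequence(VoxelComposition(0, 1.0, 0, 0), model, hard_seq)
        assert sig.intensities.shape == (5, 4)
        path = tmp_path / "sig.csv"
        sig.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(df.values, sig.intensities)
        with pytest.raises(ValueError):
            bp.SignalMatrix(intensities=np.full((5, 4), np.nan),
                            te_ms=hard_seq.te_ms, td_ms=hard_seq.td_ms)
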