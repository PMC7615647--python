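import numpy as np
import pytest
from scipy import stats

from kymotrace import synth
from kymotrace.mechanics import EWLCParams, ewlc_length


class TestSimulateTrajectory:
    def test_static_constant(self, tether):
        em = synth.EmitterModel(kind="static", start_position_um=5.0)
        t = synth.simulate_trajectory(em, tether, 100, 0.25, seed=1)
        assert np.all(t.positions_um == 5.0)

    def test_diffusive_increment_variance(self, tether):
        em = synth.EmitterModel(
            kind="diffusive", D_true_um2_s=0.04, start_position_um=8.0
        )
        t = synth.simulate_trajectory(em, tether, 10_001, 0.25, seed=2)
        inc = np.diff(t.positions_um)
        # 2 D dt = 0.02 um^2; chi2 bounds at n = 1e4
        assert inc.var() == pytest.approx(0.02, rel=0.05)

    def test_variance_ratio_test(self, tether):
        em = synth.EmitterModel(
            kind="diffusive", D_true_um2_s=0.04, start_position_um=8.0
        )
        t = synth.simulate_trajectory(em, tether, 10_001, 0.25, seed=3)
        inc = np.diff(t.positions_um)
        n = inc.size
        ratio = n * inc.var() / 0.02
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n - 1)
        assert lo < ratio < hi

    def test_reflecting_obstacle(self):
        teth = synth.TetherModel(obstacle_positions_um=(5.0,))
        em = synth.EmitterModel(
            kind="diffusive", D_true_um2_s=0.1, start_position_um=4.0
        )
        t = synth.simulate_trajectory(em, teth, 2000, 0.25, seed=4)
        assert np.all(t.positions_um <= 5.0)

    def test_directed_velocity(self, tether):
        em = synth.EmitterModel(kind="directed", velocity_um_s=0.2, start_position_um=2.0)
        t = synth.simulate_trajectory(em, tether, 50, 0.25, seed=5)
        np.testing.assert_allclose(
            t.positions_um, 2.0 + 0.2 * t.times_s, atol=1e-12
        )

    def test_start_outside_tether(self, tether):
        em = synth.EmitterModel(start_position_um=100.0)
        with pytest.raises(ValueError, match="outside tether"):
            synth.simulate_trajectory(em, tether, 10, 0.25, seed=6)

    def test_dwell_truncation(self, tether):
        em = synth.EmitterModel(kind="static", start_position_um=5.0, dwell_mean_s=2.0)
        t = synth.simulate_trajectory(em, tether, 10_000, 0.25, seed=7)
        assert len(t) < 10_000

    def test_determinism(self, tether):
        em = synth.EmitterModel(kind="diffusive", D_true_um2_s=0.05, start_position_um=5.0)
        a = synth.simulate_trajectory(em, tether, 100, 0.25, seed=8)
        b = synth.simulate_trajectory(em, tether, 100, 0.25, seed=8)
        np.testing.assert_array_equal(a.positions_um, b.positions_um)


class TestRenderKymograph:
    def test_background_only(self, tether):
        kymo, truth = synth.render_kymograph(
            [], tether, background_counts=10.0, seed=1, n_lines=50
        )
        assert truth.empty
        mean = kymo.channels["eGFP"].mean()
        assert mean == pytest.approx(10.0, abs=0.3)

    def test_static_emitter_peak_column(self, tether):
        em = synth.EmitterModel(kind="static", start_position_um=5.05, photons_per_line=2000)
        t = synth.simulate_trajectory(em, tether, 100, 0.25, seed=2)
        kymo, truth = synth.render_kymograph([t], tether, seed=3, n_lines=100)
        col_mean = kymo.channels["eGFP"].mean(axis=0)
        # 5.05 um at 100 nm px with half-pixel centering -> column 50
        assert int(np.argmax(col_mean)) == 50

    def test_two_emitters_two_maxima(self, tether):
        ems = [
            synth.EmitterModel(kind="static", start_position_um=4.05, photons_per_line=2000),
            synth.EmitterModel(kind="static", start_position_um=6.05, photons_per_line=2000),
        ]
        trajs = [
            synth.simulate_trajectory(em, tether, 50, 0.25, seed=i, traj_id=i)
            for i, em in enumerate(ems)
        ]
        kymo, _ = synth.render_kymograph(trajs, tether, seed=5, n_lines=50)
        col_mean = kymo.channels["eGFP"].mean(axis=0)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(col_mean, height=col_mean.max() / 3, distance=5)
        assert len(peaks) == 2
        assert set(peaks) == {40, 60}

    def test_saturated_bead_margins(self, tether_with_beads):
        kymo, _ = synth.render_kymograph(
            [], tether_with_beads, seed=1, n_lines=20
        )
        img = kymo.channels["eGFP"]
        assert np.all(img[:, :5] == 65535.0)
        assert np.all(img[:, -5:] == 65535.0)

    def test_determinism(self, tether):
        a, _ = synth.render_kymograph([], tether, seed=9, n_lines=20)
        b, _ = synth.render_kymograph([], tether, seed=9, n_lines=20)
        np.testing.assert_array_equal(a.channels["eGFP"], b.channels["eGFP"])


class TestSimulateFec:
    def test_no_rips_matches_model(self, tether):
        p = EWLCParams.from_bp(48_502)
        curve, truth = synth.simulate_fec(tether, p, rips=[], noise_sd_nm=0.0, seed=1)
        assert truth.empty
        expected = ewlc_length(curve.force_pN, p) / 1000.0
        np.testing.assert_allclose(curve.distance_um, expected, atol=1e-6)

    def test_147bp_rip_extends_contour(self, tether):
        p = EWLCParams.from_bp(48_502)
        curve, truth = synth.simulate_fec(
            tether, p, rips=[(15.0, 147)], noise_sd_nm=0.0, seed=2
        )
        assert truth.delta_Lc_nm.iloc[0] == pytest.approx(147 * 0.34)
        g_lo = curve.force_pN < 15.0
        g_hi = curve.force_pN >= 15.0
        lc_lo = curve.distance_um[g_lo] * 1000 / (
            ewlc_length(curve.force_pN[g_lo], p) / p.Lc_nm
        )
        lc_hi = curve.distance_um[g_hi] * 1000 / (
            ewlc_length(curve.force_pN[g_hi], p) / p.Lc_nm
        )
        assert np.mean(lc_hi) - np.mean(lc_lo) == pytest.approx(49.98, abs=0.1)

    def test_two_rips_additive(self, tether):
        p = EWLCParams.from_bp(48_502)
        _, truth = synth.simulate_fec(
            tether, p, rips=[(10.0, 73.5), (20.0, 147)], noise_sd_nm=0.0, seed=3
        )
        assert truth.delta_Lc_nm.sum() == pytest.approx((73.5 + 147) * 0.34)

    def test_rip_outside_grid_rejected(self, tether):
        p = EWLCParams.from_bp(48_502)
        with pytest.raises(ValueError, match="outside force grid"):
            synth.simulate_fec(tether, p, rips=[(100.0, 147)], seed=4)


class TestSimulateDwells:
    def test_sample_mean(self):
        dwells = synth.simulate_dwells(27.2, 100_000, frame_s=0.01, seed=1)
        mean = np.mean([d for d, _ in dwells])
        assert mean == pytest.approx(27.2, rel=0.01)

    def test_censored_fraction(self):
        mean_s = 20.0
        dwells = synth.simulate_dwells(
            mean_s, 100_000, frame_s=0.01, observation_limit_s=0.5 * mean_s, seed=2
        )
        frac = np.mean([c for _, c in dwells])
        assert frac == pytest.approx(np.exp(-0.5), abs=0.01)

    def test_empty(self):
        assert synth.simulate_dwells(10.0, 0, seed=3) == []

    def test_frame_discretization(self):
        dwells = synth.simulate_dwells(5.0, 100, frame_s=0.25, seed=4)
        for d, _ in dwells:
            assert d / 0.25 == pytest.approx(round(d / 0.25))


class TestSimulateBleachTrace:
    def test_zero_steps_constant(self):
        trace, truth = synth.simulate_bleach_trace(0, noise=False, seed=1)
        assert truth["n_steps"] == 0
        assert np.all(trace == trace[0])

    def test_three_steps_noiseless(self):
        trace, truth = synth.simulate_bleach_trace(3, noise=False, seed=2)
        downs = np.flatnonzero(np.diff(trace) < 0)
        assert len(downs) == 3

    def test_final_level_is_background(self):
        trace, truth = synth.simulate_bleach_trace(
            2, background=20.0, noise=False, seed=3
        )
        assert trace[-1] == 20.0


class TestSimulateNucleation:
    def test_poisson_mean(self):
        counts = [
            len(synth.simulate_nucleation(0.277, 5.374, 60.0, seed=s))
            for s in range(10_000)
        ]
        expected = 0.277 * 5.374  # events per minute over one minute
        assert np.mean(counts) == pytest.approx(expected, rel=0.03)

    def test_zero_rate(self):
        assert len(synth.simulate_nucleation(0.0, 5.374, 60.0, seed=1)) == 0

    def test_junction_weight(self):
        events = synth.simulate_nucleation(
            10.0, 5.374, 600.0, seed=2, junction_weight=(0.6, 0.8)
        )
        pos = events.position_knt.to_numpy()
        outer = (pos < 0.6) | (pos > 5.374 - 0.6)
        assert outer.mean() > 0.5
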