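import numpy as np
import pytest

from kymotrace import kinetics, synth
from kymotrace.io import Kymograph, Trajectory
from kymotrace.kinetics import (
    EventRecord,
    PositionProfile,
    binding_frequency,
    classify_event_order,
    collision_outcomes,
    detect_events,
    diffusive_fraction,
    fit_dwell,
    junction_stat,
    nucleation_rate,
    position_profile,
)


def blank_kymo(n_lines=60, width=120, bg=10.0, seed=0):
    rng = np.random.default_rng(seed)
    img = rng.poisson(bg, size=(n_lines, width)).astype(float)
    return Kymograph(channels={"eGFP": img}, pixel_size_nm=100.0, line_time_s=0.25)


def plant_event(kymo, start, end, col, amplitude=200.0):
    kymo.channels["eGFP"][start : end + 1, col - 1 : col + 2] += amplitude
    return (start, end, col)


class TestDetectEvents:
    def test_blank_no_events(self):
        assert detect_events(blank_kymo(), "eGFP") == []

    def test_planted_events_recovered(self):
        kymo = blank_kymo(n_lines=100, width=160, seed=1)
        planted = [
            plant_event(kymo, 5, 20, 30),
            plant_event(kymo, 10, 40, 70),
            plant_event(kymo, 50, 60, 30),
            plant_event(kymo, 70, 90, 110),
            plant_event(kymo, 30, 55, 140),
        ]
        events = detect_events(kymo, "eGFP")
        assert len(events) == 5
        for (s, e, c), ev in zip(sorted(planted), sorted(events, key=lambda x: (x.start_s, x.position_um))):
            # boundary jitter from adjacent noise pixels: allow 2 lines
            assert ev.start_s == pytest.approx(s * 0.25, abs=0.5)
            assert ev.end_s == pytest.approx(e * 0.25, abs=0.5)

    def test_censored_flag(self):
        kymo = blank_kymo(n_lines=50, seed=2)
        plant_event(kymo, 30, 49, 60)
        events = detect_events(kymo, "eGFP")
        assert len(events) == 1
        assert events[0].censored

    def test_region_restriction(self):
        kymo = blank_kymo(n_lines=50, width=120, seed=3)
        plant_event(kymo, 5, 30, 20)
        plant_event(kymo, 5, 30, 100)
        events = detect_events(kymo, "eGFP", region_um=(8.0, 12.0))
        assert len(events) == 1
        assert events[0].position_um == pytest.approx(10.05, abs=0.2)


class TestClassifyEventOrder:
    def ev(self, channel, start, pos, end=None):
        return EventRecord(channel=channel, start_s=start,
                           end_s=end if end is not None else start + 10.0,
                           position_um=pos)

    def test_simultaneous_co_complex(self):
        counts = classify_event_order(
            [self.ev("BRCA2", 2.0, 5.0)], [self.ev("RAD51", 2.0, 5.0)],
            line_time_s=0.25, pixel_size_nm=100.0,
        )
        assert counts["co_complex"] == 1

    def test_brca2_first(self):
        counts = classify_event_order(
            [self.ev("BRCA2", 2.5, 5.0)], [self.ev("RAD51", 12.5, 5.0)],
            line_time_s=0.25, pixel_size_nm=100.0,
        )
        assert counts["brca2_first"] == 1

    def test_brca2_on_rad51(self):
        counts = classify_event_order(
            [self.ev("BRCA2", 12.5, 5.0)], [self.ev("RAD51", 2.5, 5.0)],
            line_time_s=0.25, pixel_size_nm=100.0,
        )
        assert counts["brca2_on_rad51"] == 1

    def test_alone_when_far_away(self):
        counts = classify_event_order(
            [self.ev("BRCA2", 2.0, 5.0)], [self.ev("RAD51", 2.0, 9.0)],
            line_time_s=0.25, pixel_size_nm=100.0,
        )
        assert counts["brca2_alone"] == 1

    def test_symmetric_under_relabel(self):
        a = [self.ev("BRCA2", 2.0, 5.0)]
        b = [self.ev("RAD51", 2.1, 5.0)]
        c1 = classify_event_order(a, b, 0.25, 100.0)
        c2 = classify_event_order(b, a, 0.25, 100.0, labels=("rad51", "brca2"))
        assert c1["co_complex"] == c2["co_complex"] == 1

    def test_proportion_recovery(self):
        rng = np.random.default_rng(8)
        a, b = [], []
        for i in range(100):
            pos = 1.0 + 0.3 * i  # spaced beyond the colocalization radius
            start = float(rng.uniform(0, 50))
            a.append(self.ev("BRCA2", start, pos))
            dt = 0.0 if i < 80 else 10.0
            b.append(self.ev("RAD51", start + dt, pos))
        counts = classify_event_order(a, b, 0.25, 100.0)
        assert counts["co_complex"] == 80
        assert counts["brca2_first"] == 20


class TestFitDwell:
    @pytest.mark.parametrize("tau", [27.2, 101.9])
    def test_tau_recovery(self, tau):
        dwells = synth.simulate_dwells(tau, 10_000, frame_s=0.25, seed=int(tau * 10))
        fit = fit_dwell(dwells, bin_width_s=7.0)
        assert fit.tau_s == pytest.approx(tau, rel=0.05)

    def test_paper_sample_sizes_median_within_10pct(self):
        # n = 104 at tau 27.2 and n = 62 at tau 101.9 (scaled to 40 replicates)
        for tau, n in ((27.2, 104), (101.9, 62)):
            estimates = []
            for rep in range(40):
                dwells = synth.simulate_dwells(tau, n, frame_s=0.25, seed=rep)
                try:
                    estimates.append(fit_dwell(dwells).tau_s)
                except ValueError:
                    continue
            med = np.median(estimates)
            assert abs(med - tau) / tau < 0.10

    def test_degenerate_input_flagged(self):
        dwells = [(14.0, False)] * 20
        fit = fit_dwell(dwells)
        assert fit.tau_s > 0
        assert fit.r_squared <= 1.0

    def test_too_few_events(self):
        with pytest.raises(ValueError, match="uncensored"):
            fit_dwell([(5.0, False)] * 5)

    def test_censored_excluded(self):
        dwells = [(float(5 + i), False) for i in range(20)] + [(100.0, True)] * 10
        fit = fit_dwell(dwells)
        assert fit.n_events == 20
        assert fit.n_censored == 10


class TestNucleationRate:
    def test_zero_events(self):
        assert nucleation_rate([], 5.374, 60.0) == 0.0

    def test_direct_arithmetic(self):
        rate = nucleation_rate([10.0, 30.0, 55.0], 5.374, 60.0)
        assert rate == pytest.approx(3 / 5.374)

    def test_events_outside_window_ignored(self):
        rate = nucleation_rate([10.0, 70.0], 5.374, 60.0)
        assert rate == pytest.approx(1 / 5.374)

    def test_recovery_at_paper_rate(self):
        # 600-s windows keep the Monte-Carlo SE of the mean under 1%
        rates = []
        for s in range(1000):
            ev = synth.simulate_nucleation(0.277, 5.374, 600.0, seed=s)
            rates.append(nucleation_rate(ev.time_s.to_numpy(), 5.374, 600.0))
        assert np.mean(rates) == pytest.approx(0.277, rel=0.02)


class TestBindingFrequency:
    def ev(self, start):
        return EventRecord(channel="eGFP", start_s=start, end_s=start + 1,
                           position_um=1.0)

    def test_direct_arithmetic(self):
        events = [self.ev(i * 10.0) for i in range(6)]
        out = binding_frequency(events, region_length_um=3.0, observation_s=120.0)
        assert out["per_um_min"] == pytest.approx(1.0)

    def test_empty(self):
        assert binding_frequency([], 3.0, 60.0)["per_um_min"] == 0.0

    def test_doubling_window_halves(self):
        events = [self.ev(5.0)] * 4
        f1 = binding_frequency(events, 2.0, 60.0)["per_um_min"]
        f2 = binding_frequency(events, 2.0, 120.0)["per_um_min"]
        assert f2 == pytest.approx(f1 / 2)

    def test_knt_units(self):
        out = binding_frequency([self.ev(0.0)], 2.0, 60.0, gap_knt=5.374)
        assert out["per_knt_min"] == pytest.approx(1 / 5.374)


class TestPositionProfile:
    def make_gap_kymo(self, signal_cols=None, width=80, n_lines=60, bg=5.0, seed=0):
        rng = np.random.default_rng(seed)
        img = rng.poisson(bg, size=(n_lines, width)).astype(float)
        if signal_cols is not None:
            img[:, signal_cols] += 500.0
        return Kymograph(channels={"eGFP": img}, pixel_size_nm=100.0, line_time_s=0.25)

    def test_bin_count_for_5374nt_gap(self):
        kymo = self.make_gap_kymo(signal_cols=slice(10, 64))
        prof = position_profile(kymo, "eGFP", (1.0, 6.374), 5374, bin_nt=200)
        assert prof.n_bins == 27

    def test_fractions_sum_to_one(self):
        kymo = self.make_gap_kymo(signal_cols=slice(10, 64), seed=3)
        prof = position_profile(kymo, "eGFP", (1.0, 6.374), 5374)
        assert prof.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_signal_uniform_fractions(self):
        kymo = self.make_gap_kymo(signal_cols=slice(10, 64), seed=4)
        prof = position_profile(kymo, "eGFP", (1.0, 6.374), 5374)
        assert np.allclose(prof.fractions, 1 / 27, atol=0.25 / 27 * 3)

    def test_signal_at_5prime_end(self):
        # all signal in the outer 600 nt at the high-coordinate end
        kymo = self.make_gap_kymo(width=80, seed=5)
        kymo.channels["eGFP"][:, 58:64] += 2000.0
        prof = position_profile(kymo, "eGFP", (1.0, 6.374), 5374)
        assert prof.fractions[-3:].sum() > 0.9


class TestJunctionStat:
    def uniform_profile(self):
        edges = np.arange(0, 28) * 200.0
        edges[-1] = 5374.0
        return PositionProfile(bin_edges_nt=edges, fractions=np.full(27, 1 / 27))

    def test_uniform_groups_equal(self):
        stat = junction_stat([self.uniform_profile()] * 3)
        assert stat["mean_3prime"] == pytest.approx(stat["mean_middle"])
        assert stat["mean_5prime"] == pytest.approx(stat["mean_middle"])

    def test_middle_bin_count(self):
        stat = junction_stat([self.uniform_profile()])
        assert stat["n_middle_bins"] == 21

    def test_5prime_bias_detected(self):
        rng = np.random.default_rng(6)
        profiles = []
        for _ in range(11):
            f = np.full(27, 1.0) + rng.normal(0, 0.05, 27)
            f[-3:] += 2.0
            f = np.clip(f, 0, None)
            f /= f.sum()
            edges = np.arange(0, 28) * 200.0
            edges[-1] = 5374.0
            profiles.append(PositionProfile(bin_edges_nt=edges, fractions=f))
        stat = junction_stat(profiles)
        assert stat["mean_5prime"] > stat["mean_middle"]
        assert stat["p_5prime_vs_middle"] < 0.05


class TestCollisionOutcomes:
    def test_never_near_obstacle(self):
        t = Trajectory(0, "eGFP", np.arange(20) * 0.25, np.full(20, 2.0))
        counts = collision_outcomes(t, [10.0])
        assert sum(counts.values()) == 0

    def test_reflecting_never_bypasses(self):
        teth = synth.TetherModel(obstacle_positions_um=(5.0,), obstacle_bypass_prob=0.0)
        em = synth.EmitterModel(kind="diffusive", D_true_um2_s=0.1, start_position_um=4.5)
        n_bypass = 0
        for s in range(20):
            t = synth.simulate_trajectory(em, teth, 500, 0.25, seed=s)
            n_bypass += collision_outcomes(t, [5.0])["bypassed"]
        assert n_bypass == 0

    def test_bypass_probability_recovery(self):
        teth = synth.TetherModel(obstacle_positions_um=(5.0,), obstacle_bypass_prob=0.05)
        em = synth.EmitterModel(kind="diffusive", D_true_um2_s=0.1, start_position_um=4.5)
        stats = {"blocked": 0, "bypassed": 0, "dissociated_at_obstacle": 0}
        for s in range(40):
            t = synth.simulate_trajectory(em, teth, 500, 0.25, seed=100 + s)
            for k, v in collision_outcomes(t, [5.0]).items():
                stats[k] += v
        total = sum(stats.values())
        assert total > 100
        frac = stats["bypassed"] / total
        # binomial check around 0.05; generous 3-sigma bound
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)

    def test_dissociation_at_obstacle(self):
        x = np.concatenate([np.linspace(2.0, 4.9, 10), [4.95]])
        t = Trajectory(0, "eGFP", np.arange(len(x)) * 0.25, x)
        counts = collision_outcomes(t, [5.0])
        assert counts["dissociated_at_obstacle"] == 1


class TestDiffusiveFraction:
    def traj_at(self, pos):
        return Trajectory(0, "eGFP", np.arange(10) * 0.25, np.full(10, pos))

    def test_all_static(self):
        entries = [("static", self.traj_at(11.0))] * 4
        out = diffusive_fraction(entries, (10.0, 12.0))
        assert out["ssDNA"] == 0.0

    def test_half_mobile(self):
        entries = [("free", self.traj_at(11.0)), ("static", self.traj_at(11.0))]
        out = diffusive_fraction(entries, (10.0, 12.0))
        assert out["ssDNA"] == 0.5

    def test_region_assignment(self):
        entries = [("free", self.traj_at(11.0)), ("static", self.traj_at(2.0))]
        out = diffusive_fraction(entries, (10.0, 12.0))
        assert out["ssDNA"] == 1.0
        assert out["dsDNA"] == 0.0
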