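"""State classification, residence statistics and population read-outs."""

import numpy as np
import pytest

import nanogsim as ng
from nanogsim.observables import LOW, HIGH, StateThresholds
from nanogsim.simulate import SimulationConfig, Trajectory


def synthetic_traj(times, values, params):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    return Trajectory(times=times, os=np.full_like(values, 50.0),
                      n=values, x=None, params=params, seed=0)


class TestThresholds:
    def test_default_band_straddles_unstable_point(self, fluct,
                                                   fluct_thresholds):
        th = fluct_thresholds
        assert th.cut == pytest.approx(0.6475, abs=1e-3)
        assert th.high_exit < th.cut < th.low_exit
        assert th.low_exit / th.cut == pytest.approx(th.cut / th.high_exit)

    def test_band_inside_stable_levels(self, fluct, osc, osc_thresholds,
                                       fluct_thresholds, limit_cycle):
        assert 0.0974 < fluct_thresholds.high_exit
        assert fluct_thresholds.low_exit < 13.34
        assert limit_cycle.n_min < osc_thresholds.high_exit
        assert osc_thresholds.low_exit < limit_cycle.n_max

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            StateThresholds(low_exit=0.5, high_exit=0.8)


class TestClassifyStates:
    def test_constant_high_trace_one_censored_record(self, fluct,
                                                     fluct_thresholds):
        traj = synthetic_traj([0, 1, 2, 3], [13.3] * 4, fluct)
        states, recs = ng.classify_states(traj, fluct_thresholds)
        assert all(s == HIGH for s in states)
        assert len(recs) == 1 and recs[0].censored
        assert recs[0].duration == pytest.approx(3.0)

    def test_square_wave_yields_expected_records(self, fluct,
                                                 fluct_thresholds):
        """A trace crossing both thresholds n times produces exactly n+1
        alternating records."""
        period = 2.0
        reps = 5
        t, v = [], []
        for k in range(reps):
            t += [k * period, k * period + 1.0]
            v += [13.0, 0.01]
        traj = synthetic_traj(t, v, fluct)
        _, recs = ng.classify_states(traj, fluct_thresholds)
        assert len(recs) == 2 * reps
        assert [r.state for r in recs[:4]] == [HIGH, LOW, HIGH, LOW]
        inner = recs[1:-1]
        assert all(not r.censored for r in inner)
        assert recs[0].censored and recs[-1].censored

    def test_hysteresis_suppresses_chatter(self, fluct, fluct_thresholds):
        th = fluct_thresholds
        mid = th.cut
        # oscillating inside the band must not change state
        t = np.arange(10.0)
        v = np.where(np.arange(10) % 2 == 0, mid * 1.05, mid * 0.95)
        traj = synthetic_traj(t, np.concatenate([[13.0], v[1:]]), fluct)
        _, recs = ng.classify_states(traj, th)
        assert len(recs) == 1 and recs[0].state == HIGH

    def test_short_trace_rejected(self, fluct, fluct_thresholds):
        with pytest.raises(ValueError):
            ng.classify_states(synthetic_traj([0.0], [1.0], fluct),
                               fluct_thresholds)

    def test_duration_conservation(self, fluct, fluct_thresholds):
        cfg = SimulationConfig(dt=1e-4, t_end=1.0, seed=13)
        traj = ng.simulate_cell(fluct, cfg)
        _, recs = ng.classify_states(traj, fluct_thresholds)
        total = sum(r.duration for r in recs)
        assert total == pytest.approx(traj.times[-1] - traj.times[0])

    def test_deterministic_oscillation_fixed_residence(self, osc,
                                                       osc_thresholds,
                                                       limit_cycle):
        """With sigma=0 the residence times are fixed: all uncensored LOW
        durations agree, as do the HIGH durations."""
        p = osc.with_(sigma=0.0)
        cfg = SimulationConfig(dt=2e-3, t_end=6 * limit_cycle.period,
                               seed=0, record_every=10,
                               initial_condition="cycle")
        traj = ng.simulate_cell(p, cfg)
        _, recs = ng.classify_states(traj, osc_thresholds)
        lows = [r.duration for r in recs if r.state == LOW and
                not r.censored]
        highs = [r.duration for r in recs if r.state == HIGH and
                 not r.censored]
        assert len(lows) >= 4 and len(highs) >= 4
        assert np.std(lows) / np.mean(lows) < 0.01
        assert np.std(highs) / np.mean(highs) < 0.01
        # LOW + HIGH sojourn = one full period
        assert np.mean(lows) + np.mean(highs) == pytest.approx(
            limit_cycle.period, rel=0.02)


class TestFractionLow:
    def test_all_high_gives_zero(self, fluct_thresholds):
        assert ng.fraction_low(np.full(100, 13.3), fluct_thresholds) == 0.0

    def test_reordering_invariance(self, fluct_thresholds):
        rng = np.random.default_rng(0)
        snap = rng.lognormal(0.0, 1.5, size=500)
        f1 = ng.fraction_low(snap, fluct_thresholds)
        f2 = ng.fraction_low(rng.permutation(snap), fluct_thresholds)
        assert f1 == f2

    def test_joint_rescaling_invariance(self, fluct_thresholds):
        rng = np.random.default_rng(1)
        snap = rng.lognormal(0.0, 1.5, size=500)
        th = fluct_thresholds
        c = 7.3
        scaled = StateThresholds(low_exit=th.low_exit * c,
                                 high_exit=th.high_exit * c)
        assert ng.fraction_low(snap, th) == ng.fraction_low(snap * c,
                                                            scaled)

    def test_empty_snapshot_rejected(self, fluct_thresholds):
        with pytest.raises(ValueError):
            ng.fraction_low([], fluct_thresholds)


class TestResidenceStatistics:
    def test_hand_arithmetic(self, fluct):
        recs = [
            ng.ResidenceRecord(LOW, 0.0, 2.0, censored=True),
            ng.ResidenceRecord(HIGH, 2.0, 4.0, censored=False),
            ng.ResidenceRecord(LOW, 4.0, 6.0, censored=False),
            ng.ResidenceRecord(HIGH, 6.0, 10.0, censored=False),
            ng.ResidenceRecord(LOW, 10.0, 14.0, censored=False),
        ]
        stats = ng.residence_statistics(recs, p=fluct)
        assert stats[LOW]["n"] == 2
        assert stats[LOW]["mean_raw"] == pytest.approx(3.0)
        assert stats[LOW]["cv"] == pytest.approx(1.0 / 3.0)
        assert stats[LOW]["censored_n"] == 1
        assert stats[LOW]["mean_tau"] == pytest.approx(3.0 * 270.0)
        assert stats[HIGH]["mean_raw"] == pytest.approx(3.0)

    def test_all_censored_raises(self, fluct):
        recs = [ng.ResidenceRecord(LOW, 0.0, 1.0, censored=True)]
        with pytest.raises(ValueError, match="LOW"):
            ng.residence_statistics(recs)

    def test_fluctuation_low_sojourns_exponential_cv(self, fluct_residence):
        """Noise-driven switching leaves the exponential signature
        CV ~ 1 on the LOW durations (>=400 sojourns)."""
        st = fluct_residence[LOW]
        assert st["n"] >= 400
        assert st["cv"] == pytest.approx(1.0, abs=0.25)

    def test_exponential_memorylessness_of_low_durations(
            self, fluct, fluct_thresholds):
        """LOW sojourn durations beyond the classifier resolution are
        exponential: conditional on exceeding half the mean, the excess
        duration passes a KS test against the exponential law at 1%.
        (Sojourns at the resolution of the hysteresis band itself are
        crossing artifacts and carry no kinetic information.)"""
        from scipy.stats import kstest
        cfg = SimulationConfig(dt=5e-5, t_end=170.0, seed=31)
        traj = ng.simulate_cell(fluct, cfg)
        _, recs = ng.classify_states(traj, fluct_thresholds)
        durs = np.array([r.duration for r in recs
                         if r.state == LOW and not r.censored])
        assert len(durs) >= 500
        c = 0.5 * durs.mean()
        excess = durs[durs > c] - c
        assert len(excess) >= 200
        res = kstest(excess, "expon", args=(0.0, excess.mean()))
        assert res.pvalue > 0.01

    def test_oscillation_low_sojourns_peaked(self, osc_residence):
        """Limit-cycle switching: narrowly peaked LOW durations whose mode
        sits at the mean (symmetric, unlike the exponential case)."""
        st = osc_residence[LOW]
        assert st["cv"] < 0.5
        edges, counts = st["hist_edges"], st["hist_counts"]
        i = int(np.argmax(counts))
        mode = 0.5 * (edges[i] + edges[i + 1])
        assert mode == pytest.approx(st["mean_raw"], rel=0.3)


class TestPopulationHistogram:
    def test_point_mass_single_bin_unimodal(self):
        h = ng.population_histogram(np.full(50, 3.0))
        assert h.counts.tolist() == [50]
        assert not h.bimodal

    def test_counts_conserved_density_normalized(self, fluct):
        rng = np.random.default_rng(3)
        snap = np.concatenate([rng.lognormal(-2, 0.3, 200),
                               rng.lognormal(2.6, 0.3, 800)])
        h = ng.population_histogram(snap)
        assert h.counts.sum() == 1000
        area = np.trapezoid(h.density, h.density_grid)
        assert area == pytest.approx(1.0, abs=0.02)
        assert h.bimodal

    def test_fluctuation_stationary_snapshot_bimodal(self, fluct):
        """Free-running integration (output truncation) shows the two
        Nanog modes of the stationary population."""
        ens = ng.stationary_ensemble(fluct, 1200, seed=9, dt=1e-4,
                                     clamp="output")
        h = ng.population_histogram(ens.snapshot(-1))
        assert h.bimodal

    def test_oscillation_stationary_snapshot_bimodal(self, osc):
        ens = ng.stationary_ensemble(osc, 1200, seed=9)
        h = ng.population_histogram(ens.snapshot(-1))
        assert h.bimodal

    def test_low_fraction_monotone_in_noise(self, fluct, fluct_thresholds):
        """The Nanog-low mass grows with the noise amplitude (distribution
        shape responds to sigma)."""
        fracs = []
        for sig in (8.0, 16.0):
            ens = ng.stationary_ensemble(fluct.with_(sigma=sig), 800,
                                         seed=9, dt=1e-4)
            fracs.append(ng.fraction_low(ens.snapshot(-1),
                                         fluct_thresholds))
        assert fracs[0] < fracs[1]
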