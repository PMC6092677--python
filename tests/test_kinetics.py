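"""Kinetic simulator: exactness, unidirectional maturation, blockade
experiments and population generation."""

import math

import numpy as np
import pandas as pd
import pytest

from tocky import (
    MeasurementModel,
    MixtureComponent,
    TimerKineticParams,
    TranscriptionProgram,
    derive_thresholds,
    simulate_decay_experiment,
    simulate_population,
    simulate_trajectory,
    steady_state,
)
from tocky.transform import polar_from_normalised


class TestParams:
    def test_derived_rates(self, params):
        assert params.k_blue == pytest.approx(math.log(2) / 4.1)
        assert params.k_red == pytest.approx(math.log(2) / 122)
        assert params.maturation_rate == params.k_blue  # default fraction 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"blue_loss_halflife": 0.0},
            {"red_halflife": -1.0},
            {"maturation_fraction": 0.0},
            {"maturation_fraction": 1.5},
            {"translation_rate": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TimerKineticParams(**kwargs)


class TestPrograms:
    def test_rate_evaluation(self):
        prog = TranscriptionProgram.arrested(t_stop=10.0, rate=2.0)
        assert prog.rate_at(5.0) == 2.0
        assert prog.rate_at(10.0) == 0.0  # left-closed segments
        assert prog.rate_at(15.0) == 0.0

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            TranscriptionProgram(((0.0, 5.0, 1.0), (4.0, 8.0, 1.0)))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            TranscriptionProgram(((0.0, 5.0, -1.0),))

    def test_intermittent_duty_cycle(self):
        prog = TranscriptionProgram.intermittent(period=10.0, duty_cycle=0.3, t_end=50.0)
        on = sum(e - s for s, e, r in prog.segments if r > 0)
        assert on == pytest.approx(0.3 * 50.0)


class TestTrajectory:
    def test_zero_rate_program_stays_dark(self, params):
        traj = simulate_trajectory(TranscriptionProgram.silent(), params, np.linspace(0, 50, 20))
        assert np.all(traj.blue == 0) and np.all(traj.red == 0)

    def test_steady_state_red_blue_ratio(self, params):
        # closed form: B* = s a / k_B, R* = m B* / d_R -> R*/B* = 122 / 4.1
        traj = simulate_trajectory(
            TranscriptionProgram.persistent(), params, [3000.0]
        )
        assert traj.red[-1] / traj.blue[-1] == pytest.approx(122 / 4.1, rel=1e-6)
        bstar, rstar = steady_state(params)
        assert traj.blue[-1] == pytest.approx(bstar, rel=1e-6)
        assert traj.red[-1] == pytest.approx(rstar, rel=1e-6)

    def test_blue_halves_per_blue_halflife_after_arrest(self, params):
        t1 = 60.0
        traj = simulate_trajectory(
            TranscriptionProgram.arrested(t_stop=t1), params, [t1, t1 + 4.1, t1 + 8.2]
        )
        assert traj.blue[1] == pytest.approx(traj.blue[0] / 2, rel=1e-9)
        assert traj.blue[2] == pytest.approx(traj.blue[0] / 4, rel=1e-9)

    def test_matches_numerical_ode_oracle(self, ode_oracle):
        rng = np.random.default_rng(42)
        for _ in range(20):
            params = TimerKineticParams(
                mrna_halflife=rng.uniform(0.5, 3),
                blue_loss_halflife=rng.uniform(1, 10),
                maturation_fraction=rng.uniform(0.3, 1.0),
                red_halflife=rng.uniform(20, 200),
                include_mrna_stage=bool(rng.integers(2)),
            )
            kind = rng.integers(4)
            if kind == 0:
                prog = TranscriptionProgram.persistent(rng.uniform(0.5, 2))
            elif kind == 1:
                prog = TranscriptionProgram.arrested(rng.uniform(5, 30))
            elif kind == 2:
                prog = TranscriptionProgram.new_onset(rng.uniform(0, 10))
            else:
                prog = TranscriptionProgram.intermittent(
                    rng.uniform(5, 20), rng.uniform(0.2, 0.8), t_end=100.0
                )
            times = np.sort(rng.uniform(0, 80, size=8))
            traj = simulate_trajectory(prog, params, times)
            blue_ref, red_ref = ode_oracle(prog, params, times)
            scale_b = max(blue_ref.max(), 1e-12)
            scale_r = max(red_ref.max(), 1e-12)
            assert np.max(np.abs(traj.blue - blue_ref)) / scale_b < 1e-8
            assert np.max(np.abs(traj.red - red_ref)) / scale_r < 1e-8

    def test_unidirectional_maturation(self, params):
        # red can only appear after blue has been produced
        traj = simulate_trajectory(
            TranscriptionProgram.new_onset(t0=10.0), params, np.linspace(0, 30, 61)
        )
        before = traj.times <= 10.0
        assert np.all(traj.red[before] == 0)
        assert np.all(traj.blue[before] == 0)
        after = traj.times > 10.5
        assert np.all(traj.blue[after] > 0)
        assert np.all(traj.red[after] > 0)
        # red lags blue: early post-onset ratio far below steady state
        i = np.searchsorted(traj.times, 11.0)
        assert traj.red[i] / traj.blue[i] < 0.1 * (122 / 4.1)

    def test_decay_monotone_without_transcription(self, params):
        # once residual blue is negligible (many blue half-lives after
        # arrest), both colours decay monotonically
        traj = simulate_trajectory(
            TranscriptionProgram.arrested(t_stop=50.0), params, np.linspace(90, 200, 40)
        )
        assert np.all(np.diff(traj.blue) < 0)
        assert np.all(np.diff(traj.red) < 0)

    def test_mass_balance_full_maturation(self):
        # with maturation_fraction 1 and negligible red decay, every lost
        # blue unit reappears as red: B + R tracks cumulative synthesis
        params = TimerKineticParams(red_halflife=1e9)
        prog = TranscriptionProgram.arrested(t_stop=20.0, rate=1.5)
        times = np.array([5.0, 20.0, 60.0])
        traj = simulate_trajectory(prog, params, times)
        synthesised = 1.5 * params.translation_rate * np.minimum(times, 20.0)
        assert np.allclose(traj.blue + traj.red, synthesised, rtol=1e-6)

    def test_empty_time_grid_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_trajectory(TranscriptionProgram.persistent(), params, [])

    def test_angle_monotone_in_duty_cycle(self, params):
        # long-run mean Timer-Angle decreases as transcription bursts
        # become more frequent (higher duty cycle)
        bstar, rstar = steady_state(params)
        mean_angles = []
        for duty in (0.2, 0.5, 0.8):
            prog = TranscriptionProgram.intermittent(
                period=24.0, duty_cycle=duty, t_end=2000.0
            )
            times = np.linspace(960.0, 984.0, 49)  # one period, past burn-in
            traj = simulate_trajectory(prog, params, times)
            ang, _ = polar_from_normalised(traj.blue / bstar, traj.red / rstar)
            mean_angles.append(ang.mean())
        assert mean_angles[0] > mean_angles[1] > mean_angles[2]


class TestPopulation:
    def test_determinism_same_seed(self, params):
        mix = [MixtureComponent(TranscriptionProgram.persistent(), 1.0, (10.0, 100.0))]
        kw = dict(n_cells=50, params=params, noise=MeasurementModel(), seed=123)
        a = simulate_population(mix, **kw)
        b = simulate_population(mix, **kw)
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.control, b.control)

    def test_row_count_and_control_is_dark(self, params, noise_free):
        mix = [MixtureComponent(TranscriptionProgram.persistent(), 1.0, 50.0)]
        sample = simulate_population(mix, n_cells=37, params=params, noise=noise_free, seed=0)
        assert len(sample.events) == 37
        assert np.all(sample.control[["timer_blue", "timer_red"]].to_numpy() == 0)

    def test_silent_mixture_positive_fraction_matches_quantile(self, params):
        # events and control share the background distribution, so gating
        # at the control q-quantile flags ~2(1-q) of events (two channels)
        q = 0.99
        mix = [MixtureComponent(TranscriptionProgram.silent(), 1.0, 10.0)]
        sample = simulate_population(
            mix, n_cells=20000, params=params, noise=MeasurementModel(), seed=5
        )
        th = derive_thresholds(sample.control, quantile=q)
        frac = np.mean(
            (sample.events["timer_blue"] > th.blue) | (sample.events["timer_red"] > th.red)
        )
        assert frac == pytest.approx(2 * (1 - q), abs=6e-3)

    def test_empty_mixture_and_bad_n_rejected(self, params, noise_free):
        with pytest.raises(ValueError):
            simulate_population([], 10, params, noise_free)
        with pytest.raises(ValueError):
            simulate_population(
                [MixtureComponent(TranscriptionProgram.persistent())], 0, params, noise_free
            )


class TestDecayExperiments:
    def test_chx_blue_mfi_halves_per_blue_halflife(self, params):
        series = simulate_decay_experiment("chx", params, [0.0, 4.1, 8.2])
        blue = series["blue_mfi"].values
        assert blue[1] / blue[0] == pytest.approx(0.5, rel=1e-9)
        assert blue[2] / blue[0] == pytest.approx(0.25, rel=1e-9)

    def test_chx_red_rises_while_blue_decays(self, params):
        series = simulate_decay_experiment("chx", params, list(np.arange(0, 13.0, 1.0)))
        assert np.all(np.diff(series["blue_mfi"].values) < 0)
        assert np.all(np.diff(series["red_mfi"].values[:8]) > 0)

    def test_actd_ct_rises_one_cycle_per_halving(self, params):
        series = simulate_decay_experiment("actd", params, [0.0, 1.14, 2.28], ct0=20.0)
        assert series["ct"].values == pytest.approx([20.0, 21.0, 22.0])

    def test_red_washout_halves_per_red_halflife(self, params):
        series = simulate_decay_experiment("red_washout", params, [0.0, 122.0, 244.0])
        red = series["red_mfi"].values
        assert red[1] / red[0] == pytest.approx(0.5, rel=1e-9)
        assert red[2] / red[0] == pytest.approx(0.25, rel=1e-9)

    def test_unknown_kind_rejected(self, params):
        with pytest.raises(ValueError, match="unknown"):
            simulate_decay_experiment("dmso", params, [0.0, 1.0])

    def test_times_must_start_at_zero(self, params):
        with pytest.raises(ValueError):
            simulate_decay_experiment("chx", params, [1.0, 2.0])
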