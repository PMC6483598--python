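"""Rhythm-estimation tests: detrending, periodogram seeding, FFT-NLLS fits,
and the RAE-based rhythmicity call."""

import numpy as np
import pytest

from clockscreen import (
    DegenerateInputError,
    Trace,
    TraceModel,
    classify_rhythmicity,
    detrend,
    fft_seed,
    fit_fftnlls,
    simulate_trace,
)
from clockscreen.rhythm import CosineComponent, RhythmFit

from conftest import circular_error, grid_search_period

HOURS_120 = np.arange(120.0)


def make_trace(values, times=None, plant_id="t"):
    return Trace(plant_id=plant_id, times=HOURS_120 if times is None else times, values=values)


class TestTrace:
    def test_rejects_non_monotone_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Trace("x", [0.0, 2.0, 1.0], [1.0, 2.0, 3.0])

    def test_rejects_length_mismatch_and_nan(self):
        with pytest.raises(ValueError):
            Trace("x", [0.0, 1.0], [1.0])
        with pytest.raises(ValueError, match="non-finite"):
            Trace("x", [0.0, 1.0, 2.0], [1.0, np.nan, 3.0])

    def test_validate_enforces_minimum_samples(self):
        short = Trace("x", np.arange(10.0), np.ones(10))
        with pytest.raises(DegenerateInputError):
            short.validate()
        assert short.validate(min_samples=5) is short


class TestDetrend:
    @pytest.mark.parametrize(
        "values",
        [np.full(120, 100.0), 2.0 + 0.5 * HOURS_120],
        ids=["constant", "pure-line"],
    )
    def test_line_is_absorbed(self, values):
        out = detrend(make_trace(values))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_matches_closed_form_ols(self):
        # residuals of cosine + line must equal the cosine minus its own
        # closed-form regression line (the line terms cancel exactly)
        cosine = 10.0 * np.cos(2 * np.pi * HOURS_120 / 24.0)
        y = cosine + 0.5 * HOURS_120
        t = HOURS_120
        tbar, cbar = t.mean(), cosine.mean()
        slope = np.sum((t - tbar) * (cosine - cbar)) / np.sum((t - tbar) ** 2)
        expected = cosine - (cbar + slope * (t - tbar))
        out = detrend(make_trace(y))
        np.testing.assert_allclose(out.values, expected, atol=1e-8)
        assert abs(out.values.mean()) < 1e-9

    def test_too_short_raises(self):
        with pytest.raises(DegenerateInputError):
            detrend(Trace("x", [0.0, 1.0], [1.0, 2.0]))


class TestFftSeed:
    def test_dominant_peak_near_24h(self):
        seeds = fft_seed(make_trace(10 * np.cos(2 * np.pi * HOURS_120 / 24.0)))
        assert seeds, "expected at least one seed"
        assert 22.0 <= seeds[0].period <= 26.0

    def test_two_cosines_seeded_in_amplitude_order(self):
        y = 10 * np.cos(2 * np.pi * HOURS_120 / 24.0) + 5 * np.cos(
            2 * np.pi * HOURS_120 / 12.0
        )
        seeds = fft_seed(make_trace(y), max_components=2)
        assert len(seeds) == 2
        assert abs(seeds[0].period - 24.0) < 2.0
        assert abs(seeds[1].period - 12.0) < 1.0
        assert seeds[0].amplitude > seeds[1].amplitude

    def test_flat_residual_gives_empty_list(self):
        assert fft_seed(make_trace(np.zeros(120))) == []


class TestFitFftnlls:
    def test_exact_model_recovered(self):
        y = 100 + 10 * np.cos(2 * np.pi * (HOURS_120 - 2.0) / 24.0)
        fit = fit_fftnlls(make_trace(y))
        assert fit.selected is not None
        assert fit.period == pytest.approx(24.0, abs=0.05)
        assert fit.phase == pytest.approx(2.0, abs=0.1)
        assert fit.rae < 0.05
        assert classify_rhythmicity(fit) == "rhythmic"

    def test_matches_grid_search_on_damped_noisy_trace(self):
        model = TraceModel(period=26.0, damping=0.005, noise_sd=1.0)
        tr = simulate_trace(model, seed=11, plant_id="g")
        fit = fit_fftnlls(tr)
        oracle = grid_search_period(tr.times, tr.values, window=(15.0, 35.0), step=0.01)
        # the NLLS period must sit inside the brute-force profile's half-width
        assert abs(fit.period - oracle) <= 0.25
        assert abs(fit.period - 26.0) < 0.5

    def test_white_noise_called_arrhythmic(self):
        arrhythmic = 0
        n_trials = 30
        for s in range(n_trials):
            tr = simulate_trace(
                TraceModel(amplitude=0.0, noise_sd=4.0), seed=5000 + s, plant_id=f"w{s}"
            )
            fit = fit_fftnlls(tr)
            arrhythmic += classify_rhythmicity(fit) == "arrhythmic"
        assert arrhythmic >= int(0.9 * n_trials)

    def test_short_trace_raises(self):
        with pytest.raises(DegenerateInputError):
            fit_fftnlls(Trace("x", np.arange(5.0), np.ones(5)))
        with pytest.raises(DegenerateInputError, match="window"):
            fit_fftnlls(Trace("x", np.arange(10.0), np.sin(np.arange(10.0))))

    def test_phase_always_in_period_interval(self):
        for s in range(10):
            tr = simulate_trace(TraceModel(phase=20.0), seed=s, plant_id=f"p{s}")
            fit = fit_fftnlls(tr)
            if fit.selected is not None:
                assert 0.0 <= fit.phase < fit.period

    def test_one_period_delay_leaves_phase_unchanged(self):
        base = TraceModel(noise_sd=0.0, damping=0.0, period=24.0, phase=3.0)
        delayed = TraceModel(noise_sd=0.0, damping=0.0, period=24.0, phase=3.0 + 24.0)
        fit_a = fit_fftnlls(simulate_trace(base, 0))
        fit_b = fit_fftnlls(simulate_trace(delayed, 0))
        assert circular_error(fit_a.phase, fit_b.phase, 24.0) < 0.05

    def test_rae_never_decreases_with_noise(self):
        # median RAE across a seeded ladder of noise levels must be monotone
        medians = []
        for sd in (0.5, 2.0, 6.0, 12.0):
            raes = []
            for s in range(12):
                tr = simulate_trace(
                    TraceModel(noise_sd=sd), seed=900 + s, plant_id=f"n{sd}_{s}"
                )
                raes.append(fit_fftnlls(tr).rae)
            medians.append(np.median(raes))
        assert all(a <= b + 1e-9 for a, b in zip(medians, medians[1:])), medians

    def test_parameter_recovery_on_simulated_traces(self, rng):
        # tau drawn in [20, 30] at SNR >= 5: small-n version of the
        # recovery property checked in full by the acceptance suite
        tau_errs, phase_errs = [], []
        for s in range(40):
            tau = float(rng.uniform(20.0, 30.0))
            phase = float(rng.uniform(0.0, tau))
            model = TraceModel(period=tau, phase=phase, noise_sd=4.0)
            fit = fit_fftnlls(simulate_trace(model, seed=3000 + s, plant_id=f"r{s}"))
            assert fit.selected is not None
            tau_errs.append(abs(fit.period - tau))
            phase_errs.append(circular_error(fit.phase, phase, tau))
        assert np.median(tau_errs) < 0.2
        assert np.median(phase_errs) < 0.5


class TestClassifyRhythmicity:
    @staticmethod
    def _fit_with_rae(rae):
        comp = CosineComponent(period=24.0, amplitude=1.0, phase=0.0, amplitude_error=rae)
        return RhythmFit(
            plant_id="x", components=(comp,), selected=0, baseline=(0.0, 0.0),
            rss=0.0, n_obs=120,
        )

    def test_rae_above_cutoff_is_arrhythmic(self):
        assert classify_rhythmicity(self._fit_with_rae(0.61)) == "arrhythmic"

    def test_cutoff_boundary_is_strict(self):
        assert classify_rhythmicity(self._fit_with_rae(0.60)) == "rhythmic"

    def test_no_selected_component_is_arrhythmic(self):
        fit = RhythmFit(
            plant_id="x", components=(), selected=None, baseline=(0.0, 0.0),
            rss=1.0, n_obs=120,
        )
        assert classify_rhythmicity(fit) == "arrhythmic"
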