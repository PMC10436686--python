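"""ITC_CS, cut-and-swap surrogates, jackknife latency, sinusoid fits."""

import numpy as np
import pytest

from plsp.circstats import circ_abs_distance
from plsp.phase_analysis import (
    FitFailureError,
    NoCrossingError,
    fit_sinusoid,
    itc_cs,
    itc_cs_timecourse,
    jackknife_latency,
    phases_from_trials,
    sine_phase_to_cosine,
    surrogate_itc_null,
)
from plsp.synthgen import gen_phase_trials

FS = 1000.0


def itc_cs_pairwise(angles_deg):
    """Brute-force O(N^2) oracle: mean cosine over all trial pairs."""
    a = np.deg2rad(np.asarray(angles_deg, float))
    n = len(a)
    total = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            total += np.cos(a[i] - a[j])
    return 2.0 * total / (n * (n - 1))


class TestItcCs:
    @pytest.mark.parametrize("angles,expected", [
        ([33.0] * 7, 1.0),                      # identical phases
        ([0.0, 180.0], -1.0),                   # antipodal pair
        ([0.0, 90.0, 180.0, 270.0], -1.0 / 3.0),  # balanced square
    ])
    def test_fixed_cases(self, angles, expected):
        assert itc_cs(angles) == pytest.approx(expected, abs=1e-12)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(2, 80))
            angles = rng.uniform(-180, 180, n)
            assert itc_cs(angles) == pytest.approx(itc_cs_pairwise(angles),
                                                   abs=1e-12)

    def test_bounded_and_rotation_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            angles = rng.uniform(-180, 180, int(rng.integers(2, 200)))
            v = itc_cs(angles)
            assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12
            assert itc_cs(angles + 77.0) == pytest.approx(v, abs=1e-10)

    def test_uniform_phases_vanish(self):
        for seed in range(5):
            angles = gen_phase_trials(400, "uniform", seed=seed)
            assert abs(itc_cs(angles)) < 3.0 / np.sqrt(400)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            itc_cs([10.0])

    def test_timecourse_matches_per_column(self):
        rng = np.random.default_rng(2)
        mat = rng.uniform(-180, 180, (8, 5))
        tc = itc_cs_timecourse(mat)
        for j in range(5):
            assert tc[j] == pytest.approx(itc_cs(mat[:, j]), abs=1e-12)


class TestSurrogateNull:
    def _trials(self, n_trials=12, n_samp=600, seed=0):
        t = np.arange(n_samp) / FS
        base = np.cos(2 * np.pi * 10.0 * t)
        return np.tile(base, (n_trials, 1))

    def test_rotation_conserves_sample_multiset(self):
        # each surrogate trial must be a circular rotation of the original
        x = np.vstack([np.arange(50.0), np.arange(50.0, 100.0)])
        rng = np.random.default_rng(3)
        cuts = rng.integers(0, 50, 2)
        idx = (np.arange(50)[None, :] + cuts[:, None]) % 50
        rotated = x[np.arange(2)[:, None], idx]
        for i in range(2):
            assert sorted(rotated[i]) == sorted(x[i])
            assert np.array_equal(rotated[i], np.roll(x[i], -cuts[i]))

    def test_aligned_trials_beat_chance(self):
        trials = self._trials()
        angles = phases_from_trials(trials, (8.0, 12.0), FS)
        original = itc_cs_timecourse(angles)
        null = surrogate_itc_null(trials, (8.0, 12.0), FS, n_rep=300, seed=1)
        interior = slice(150, 450)
        assert np.min(original[interior]) > 0.9
        assert np.max(null.chance[interior]) < 0.2

    def test_deterministic_given_seed(self):
        trials = self._trials(n_trials=4, n_samp=300)
        a = surrogate_itc_null(trials, (8.0, 12.0), FS, n_rep=1, seed=9)
        b = surrogate_itc_null(trials, (8.0, 12.0), FS, n_rep=1, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_chance_is_mean_of_values(self):
        trials = self._trials(n_trials=4, n_samp=300)
        null = surrogate_itc_null(trials, (8.0, 12.0), FS, n_rep=5, seed=2)
        assert np.allclose(null.chance, null.values.mean(axis=0))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            surrogate_itc_null(np.zeros(100), (8, 12), FS)


class TestJackknifeLatency:
    def test_linear_ramp_onset_at_thirty_percent(self):
        # shared linear 0 -> peak ramp over 100 ms from t = 0:
        # the 30% crossing sits exactly at 30 ms
        n = 300
        wave = np.concatenate([np.linspace(0, 1, 101), np.ones(n - 101)])
        waves = np.tile(wave, (6, 1))
        lat = jackknife_latency(waves, FS, fraction=0.3, mode="onset")
        assert lat == pytest.approx(30.0, abs=1e-9)

    def test_identical_waveforms_equal_single_estimate(self):
        rng = np.random.default_rng(4)
        bump = np.abs(np.convolve(rng.standard_normal(200),
                                  np.ones(20) / 20, mode="same"))
        wave = np.concatenate([np.zeros(30), bump])
        waves = np.tile(wave, (5, 1))
        lat5 = jackknife_latency(waves, FS, mode="onset")
        lat2 = jackknife_latency(np.tile(wave, (2, 1)), FS, mode="onset")
        assert lat5 == pytest.approx(lat2, abs=1e-9)

    def test_triangular_offset_mirrors_onset(self):
        tri = np.concatenate([np.linspace(0, 1, 101),
                              np.linspace(1, 0, 101)[1:]])
        waves = np.tile(tri, (4, 1))
        onset = jackknife_latency(waves, FS, mode="onset")
        offset = jackknife_latency(waves, FS, mode="offset")
        apex_ms = 100.0
        assert offset - apex_ms == pytest.approx(apex_ms - onset, abs=1e-6)

    def test_search_window_relative_to_t0(self):
        wave = np.concatenate([np.zeros(100), np.linspace(0, 1, 101),
                               np.ones(99)])
        waves = np.tile(wave, (3, 1))
        lat = jackknife_latency(waves, FS, mode="onset",
                                search_window=(-50.0, 150.0), t0_sample=100)
        assert lat == pytest.approx(30.0, abs=1e-9)

    def test_no_crossing_identifies_subsample(self):
        waves = np.ones((3, 100))  # always above threshold: no onset
        with pytest.raises(NoCrossingError, match="subject 0"):
            jackknife_latency(waves, FS, mode="onset")

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            jackknife_latency(np.ones((1, 100)), FS)


class TestFitSinusoid:
    def test_exact_recovery(self):
        t = np.arange(1000) / FS
        y = 2.0 * np.sin(2 * np.pi * 10.0 * t + np.deg2rad(30.0)) + 1.0
        fit = fit_sinusoid(y, FS)
        assert fit.a == pytest.approx(2.0, abs=1e-6)
        assert fit.f == pytest.approx(10.0, abs=1e-6)
        assert fit.phi_deg == pytest.approx(30.0, abs=1e-4)
        assert fit.b == pytest.approx(1.0, abs=1e-6)
        assert fit.r_squared > 0.999999

    def test_noisy_recovery(self):
        t = np.arange(1000) / FS
        clean = 2.0 * np.sin(2 * np.pi * 10.0 * t + np.deg2rad(30.0)) + 1.0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(1000)
            noise *= np.sqrt(np.sum((clean - 1.0) ** 2) / np.sum(noise ** 2))
            fit = fit_sinusoid(clean + noise, FS)
            assert abs(fit.f - 10.0) < 0.3
            assert circ_abs_distance(fit.phi_deg, 30.0) < 10.0

    def test_constant_input(self):
        fit = fit_sinusoid(np.full(100, 5.0), FS)
        assert fit.b == pytest.approx(5.0)
        assert fit.a == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == 0.0

    def test_amplitude_normalized_positive(self):
        t = np.arange(1000) / FS
        y = -1.5 * np.sin(2 * np.pi * 9.0 * t)
        fit = fit_sinusoid(y, FS)
        assert fit.a == pytest.approx(1.5, abs=1e-6)
        assert circ_abs_distance(fit.phi_deg, 180.0) < 1e-3

    def test_sine_to_cosine_convention(self):
        assert sine_phase_to_cosine(90.0) == pytest.approx(0.0)
        # a sin(x + 90) = a cos(x): conventions agree at that offset
        assert sine_phase_to_cosine(30.0) == pytest.approx(-60.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fit_sinusoid(np.arange(5.0), FS)
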