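"""Epoching, spectra, noise statistics (with brute-force oracles),
Z-scores, harmonic selection and chunk summation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from fpvs import spectral
from fpvs.core import AmplitudeSpectrum, Epoch, Segment
from fpvs.spectral import (
    ADULT_RECIPE,
    INFANT_RECIPE,
    HarmonicSet,
    NoiseRecipe,
    amplitude_spectrum,
    average_epochs_by_condition,
    correct_and_zscore,
    epoch_exact_cycles,
    harmonic_range,
    noise_stats,
    select_harmonics,
    sum_harmonic_chunks,
)

# ---------------------------------------------------------------------------
# independent oracles for the noise recipes
# ---------------------------------------------------------------------------

def oracle_adult(row, target):
    """Brute-force adult recipe: 12 per side, drop the innermost bin on
    each side, then the global max and min; mean/SD (ddof=1) of the 20."""
    vals = [row[target + o] for o in range(-12, 13)
            if abs(o) >= 2]  # adjacent (+-1) and target excluded
    vals = sorted(vals)[1:-1]  # drop min and max
    arr = np.array(vals)
    assert len(arr) == 20
    return arr.mean(), arr.std(ddof=1)


def oracle_infant(row, target):
    """Brute-force infant recipe on a full spectrum row."""
    offsets = [o for o in range(-16, 17) if abs(o) >= 2]
    pts = [(o, row[target + o]) for o in offsets]
    fit_pts = [(o, v) for o, v in pts if 2 <= abs(o) <= 6]
    a = np.array([[o, 1.0] for o, _ in fit_pts])
    b = np.array([v for _, v in fit_pts])
    slope, intercept = np.linalg.lstsq(a, b, rcond=None)[0]
    detr = [(o, v - (slope * o + intercept)) for o, v in pts]
    zvals = sorted(v for o, v in detr if 6 <= abs(o) <= 16)
    zvals = zvals[1:-1]
    arr = np.array(zvals)
    # the baseline at the target is the trend's value there (intercept)
    # plus the mean residual
    return intercept + arr.mean(), arr.std(ddof=1)


def _spectrum_from_row(row):
    row = np.asarray(row, dtype=float)
    return AmplitudeSpectrum(row[None, :], 1 / 34, 200.0, ["ch"])


class TestEpoching:
    def test_exact_sample_count(self, clean_segment):
        ep = epoch_exact_cycles(clean_segment)
        assert ep.n_samples == 6800

    def test_one_hz_on_bin_34(self, clean_segment):
        spec = amplitude_spectrum(epoch_exact_cycles(clean_segment))
        assert spec.bin_of(1.0) == 34
        assert spec.bin_of(6.0) == 204

    def test_non_integer_cycles_rejected(self, clean_segment):
        with pytest.raises(ValueError):
            epoch_exact_cycles(clean_segment, duration_s=33.5)

    def test_segment_too_short(self, clean_segment):
        with pytest.raises(ValueError):
            epoch_exact_cycles(clean_segment, start_offset_s=3.0)


class TestAveraging:
    def _epoch(self, data, cond="c"):
        return Epoch(data, 200.0, [f"ch{i}" for i in range(data.shape[0])],
                     duration_s=data.shape[1] / 200.0, condition_label=cond)

    def test_identical_epochs(self):
        d = np.random.default_rng(0).normal(size=(2, 400))
        avg = average_epochs_by_condition([self._epoch(d), self._epoch(d)])
        assert np.allclose(avg["c"].data, d)

    def test_epoch_plus_negation_is_zero(self):
        d = np.random.default_rng(1).normal(size=(2, 400))
        avg = average_epochs_by_condition([self._epoch(d), self._epoch(-d)])
        assert np.allclose(avg["c"].data, 0)

    def test_noise_floor_halves_with_four_epochs(self):
        rng = np.random.default_rng(2)
        t = np.arange(6800) / 200.0
        common = np.cos(2 * np.pi * 1.0 * t)
        def make():
            return self._epoch((common + rng.normal(size=6800))[None, :])
        one = amplitude_spectrum(average_epochs_by_condition([make()])["c"])
        four = amplitude_spectrum(
            average_epochs_by_condition([make() for _ in range(4)])["c"])
        sig = one.bin_of(1.0)
        noise_bins = np.r_[100:180, 240:400]
        ratio = four.amplitudes[0, noise_bins].mean() / \
            one.amplitudes[0, noise_bins].mean()
        assert ratio == pytest.approx(0.5, abs=0.1)
        assert four.amplitudes[0, sig] == pytest.approx(
            one.amplitudes[0, sig], rel=0.1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_epochs_by_condition([
                self._epoch(np.zeros((2, 400))),
                self._epoch(np.zeros((3, 400))),
            ])


class TestAmplitudeSpectrum:
    def test_bin_width(self, clean_segment):
        spec = amplitude_spectrum(epoch_exact_cycles(clean_segment))
        assert spec.bin_width_hz == pytest.approx(1 / 34)
        assert round(spec.bin_width_hz, 3) == 0.029

    def test_unit_cosine_reads_one(self):
        t = np.arange(6800) / 200.0
        ep = Epoch(np.cos(2 * np.pi * 2.0 * t)[None, :], 200.0, ["a"], 34.0)
        spec = amplitude_spectrum(ep)
        assert spec.amplitudes[0, 68] == pytest.approx(1.0, rel=1e-12)
        others = np.delete(spec.amplitudes[0], 68)
        assert np.abs(others).max() < 1e-12

    def test_constant_epoch_dc_only(self):
        ep = Epoch(np.full((1, 6800), 5.0), 200.0, ["a"], 34.0)
        spec = amplitude_spectrum(ep)
        assert spec.amplitudes[0, 0] == pytest.approx(5.0)
        assert np.abs(spec.amplitudes[0, 1:]).max() < 1e-12


class TestNoiseStats:
    def test_adult_count_is_20(self):
        rng = np.random.default_rng(0)
        row = rng.uniform(1, 2, 300)
        vals, trend = spectral._noise_values(row, 150, ADULT_RECIPE)
        assert len(vals) == 20
        assert trend == 0.0

    def test_infant_neighborhood_is_30(self):
        offs = spectral._neighbor_offsets(INFANT_RECIPE)
        assert len(offs) == 30

    def test_all_equal_neighbors_flagged(self):
        row = np.ones(300)
        row[150] = 2.0
        mean, sd, flag = noise_stats(_spectrum_from_row(row), 150,
                                     ADULT_RECIPE)
        assert mean[0] == pytest.approx(1.0)
        assert sd[0] == 0.0
        assert flag[0]

    def test_enumerated_neighborhood_matches_oracle(self):
        # neighbors 1..24 placed symmetrically around the target
        row = np.zeros(100)
        target = 50
        left = np.arange(1, 13)[::-1]      # offsets -12..-1 get 12..1
        right = np.arange(13, 25)          # offsets 1..12 get 13..24
        for o in range(1, 13):
            row[target - o] = left[::-1][o - 1]
            row[target + o] = right[o - 1]
        mean, sd, _ = noise_stats(_spectrum_from_row(row), target,
                                  ADULT_RECIPE)
        exp_mean, exp_sd = oracle_adult(row, target)
        assert mean[0] == pytest.approx(exp_mean, abs=1e-12)
        assert sd[0] == pytest.approx(exp_sd, abs=1e-12)

    def test_margin_required(self):
        with pytest.raises(ValueError):
            noise_stats(_spectrum_from_row(np.ones(30)), 5, ADULT_RECIPE)

    @settings(max_examples=200, deadline=None)
    @given(hst.integers(min_value=0, max_value=2**32 - 1))
    def test_adult_recipe_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        row = rng.uniform(0, 10, 25)
        target = 12
        mean, sd, _ = noise_stats(_spectrum_from_row(row), target,
                                  ADULT_RECIPE)
        exp_mean, exp_sd = oracle_adult(row, target)
        assert mean[0] == pytest.approx(exp_mean, abs=1e-9)
        assert sd[0] == pytest.approx(exp_sd, abs=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(hst.integers(min_value=0, max_value=2**32 - 1))
    def test_infant_recipe_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        row = rng.uniform(0, 10, 33)
        target = 16
        mean, sd, _ = noise_stats(_spectrum_from_row(row), target,
                                  INFANT_RECIPE)
        exp_mean, exp_sd = oracle_infant(row, target)
        assert mean[0] == pytest.approx(exp_mean, abs=1e-9)
        assert sd[0] == pytest.approx(exp_sd, abs=1e-9)

    def test_infant_detrend_removes_linear_slope(self):
        # a pure linear spectrum: the noise mean equals the trend's value
        # at the target bin, the residual SD vanishes, and the corrected
        # amplitude at the target is 0
        row = 0.5 + 0.01 * np.arange(200)
        mean, sd, flag = noise_stats(_spectrum_from_row(row), 100,
                                     INFANT_RECIPE)
        assert mean[0] == pytest.approx(row[100], abs=1e-9)
        assert sd[0] < 1e-9  # may be a few ulp above exact zero


class TestCorrectAndZscore:
    def test_formula(self):
        row = np.ones(300)
        # neighbors mean 1.0; make sd 0.5 by alternating values
        offs = spectral._neighbor_offsets(ADULT_RECIPE)
        vals = np.array([1.5, 0.5] * 11)
        row[150 + offs] = vals[:len(offs)]
        row[150] = 2.0
        spec = _spectrum_from_row(row)
        mean, sd, _ = noise_stats(spec, 150, ADULT_RECIPE)
        corr, z = correct_and_zscore(spec, ADULT_RECIPE,
                                     bins=np.array([150]))
        assert corr.amplitudes[0, 150] == pytest.approx(2.0 - mean[0])
        assert z.amplitudes[0, 150] == pytest.approx(
            (2.0 - mean[0]) / sd[0])

    def test_negative_corrected_preserved(self):
        rng = np.random.default_rng(0)
        row = rng.uniform(1, 2, 300)
        row[150] = 0.0
        corr, _ = correct_and_zscore(_spectrum_from_row(row), ADULT_RECIPE,
                                     bins=np.array([150]))
        assert corr.amplitudes[0, 150] < 0

    def test_flat_spectrum_flagged(self):
        row = np.ones(300)
        corr, z = correct_and_zscore(_spectrum_from_row(row), ADULT_RECIPE,
                                     bins=np.array([150]))
        assert corr.amplitudes[0, 150] == 0.0
        assert z.amplitudes[0, 150] == 0.0  # 0/0 -> 0 by convention

    def test_sd_zero_with_signal_gives_inf(self):
        row = np.ones(300)
        row[150] = 2.0
        _, z = correct_and_zscore(_spectrum_from_row(row), ADULT_RECIPE,
                                  bins=np.array([150]))
        assert np.isinf(z.amplitudes[0, 150])

    def test_kind_check(self):
        spec = _spectrum_from_row(np.ones(300))
        corr, _ = correct_and_zscore(spec, ADULT_RECIPE, bins=np.array([150]))
        with pytest.raises(ValueError):
            correct_and_zscore(corr, ADULT_RECIPE)


def _z_spectrum(z_by_harmonic, fundamental_hz, bin_width=1 / 34,
                n_bins=2000):
    amp = np.zeros((1, n_bins))
    for k, z in z_by_harmonic.items():
        b = int(round(k * fundamental_hz / bin_width))
        amp[0, b] = z
    return AmplitudeSpectrum(amp, bin_width, 200.0, ["avg"], kind="z-scored")


class TestSelectHarmonics:
    def test_consecutive_rule(self):
        z = _z_spectrum({1: 5, 2: 4, 3: 3, 4: 2, 5: 0.5, 6: 9}, 1.0)
        hs = select_harmonics({"a": z}, 1.0, None)
        assert hs.retained_indices == [1, 2, 3, 4]

    def test_overlap_skipped_not_breaking(self):
        # harmonics 6 and 12 coincide with the 6-Hz response; Z there is
        # irrelevant and the run continues to 15
        z_by = {k: 5.0 for k in range(1, 16)}
        z_by[6] = 0.0
        z_by[12] = 0.0
        z_by[16] = 0.0
        z = _z_spectrum(z_by, 1.0)
        hs = select_harmonics({"a": z}, 1.0, 6.0, max_hz=50.0)
        assert hs.excluded_overlaps == [6, 12]
        assert hs.retained_indices == [k for k in range(1, 16)
                                       if k not in (6, 12)]
        assert hs.highest_harmonic == 15

    def test_general_response_8_harmonics(self):
        z = _z_spectrum({k: 5.0 for k in range(1, 9)}, 6.0)
        hs = select_harmonics({"a": z}, 6.0, None, max_hz=50.0)
        assert hs.n_retained == 8
        assert hs.frequencies_hz[-1] == pytest.approx(48.0)

    def test_max_over_conditions(self):
        za = _z_spectrum({1: 5, 2: 0}, 1.0)
        zb = _z_spectrum({1: 5, 2: 5, 3: 5, 4: 0}, 1.0)
        hs = select_harmonics({"a": za, "b": zb}, 1.0, None)
        assert hs.retained_indices == [1, 2, 3]

    def test_empty_flagged(self):
        z = _z_spectrum({1: 0.5}, 1.0)
        hs = select_harmonics({"a": z}, 1.0, None)
        assert hs.flagged_empty
        assert hs.retained_indices == []

    def test_multichannel_rejected(self):
        amp = np.zeros((2, 100))
        z = AmplitudeSpectrum(amp, 1 / 34, 200.0, ["a", "b"], kind="z-scored")
        with pytest.raises(ValueError):
            select_harmonics({"a": z}, 1.0, None)


class TestHarmonicRange:
    def test_six_to_fortyeight(self):
        hs = harmonic_range(6.0, 48.0)
        assert hs.n_retained == 8

    def test_oddball_range_excludes_overlaps(self):
        hs = harmonic_range(1.0, 15.0, overlap_fundamental_hz=6.0)
        assert hs.excluded_overlaps == [6, 12]
        assert len(hs.retained_indices) == 13


class TestSumChunks:
    def test_linearity(self):
        rng = np.random.default_rng(0)
        row = rng.uniform(0.5, 1.5, 3000)
        spec = _spectrum_from_row(row)
        hs = harmonic_range(1.0, 3.0)
        summed = sum_harmonic_chunks(spec, hs, ADULT_RECIPE)
        per = []
        for k in hs.retained_indices:
            b = spec.bin_of(float(k))
            mean, _, _ = noise_stats(spec, b, ADULT_RECIPE)
            per.append(spec.amplitudes[0, b] - mean[0])
        assert summed.amplitude_uv[0] == pytest.approx(sum(per), abs=1e-9)

    def test_single_harmonic_equals_pointwise(self):
        rng = np.random.default_rng(1)
        row = rng.uniform(0.5, 1.5, 3000)
        spec = _spectrum_from_row(row)
        hs = HarmonicSet(1.0, [1])
        summed = sum_harmonic_chunks(spec, hs, ADULT_RECIPE)
        b = spec.bin_of(1.0)
        mean, sd, _ = noise_stats(spec, b, ADULT_RECIPE)
        assert summed.amplitude_uv[0] == pytest.approx(
            spec.amplitudes[0, b] - mean[0], abs=1e-12)
        assert summed.z[0] == pytest.approx(
            (spec.amplitudes[0, b] - mean[0]) / sd[0], abs=1e-12)

    def test_recovery_in_pink_noise(self, schedule, adult_montage):
        from fpvs import preprocess, synth

        flat = np.ones(adult_montage.n_channels)
        amps = []
        for seed in range(10):
            comp = synth.SteadyStateComponent(
                1.0, [1.0, 0.5, 0.25], topography=flat)
            rec, _ = synth.simulate_recording(
                schedule, [comp],
                synth.NoiseModel(noise_scale=1.0), adult_montage,
                rate_hz=200, seed=seed)
            seg = preprocess.crop_segments(rec, 36.0)[0]
            spec = amplitude_spectrum(epoch_exact_cycles(seg))
            hs = harmonic_range(1.0, 3.0)
            summed = sum_harmonic_chunks(spec, hs, ADULT_RECIPE)
            amps.append(summed.amplitude_uv.mean())
        assert np.mean(amps) == pytest.approx(1.75, rel=0.10)

    def test_monotonicity_noise_free(self, schedule, adult_montage):
        from fpvs import preprocess, synth

        flat = np.ones(adult_montage.n_channels)
        values = []
        for amp in (0.5, 1.0, 2.0):
            comp = synth.SteadyStateComponent(
                1.0, [amp, amp / 2], topography=flat)
            rec, _ = synth.simulate_recording(
                schedule, [comp], synth.NoiseModel(), adult_montage,
                rate_hz=200, seed=0)
            seg = preprocess.crop_segments(rec, 36.0)[0]
            spec = amplitude_spectrum(epoch_exact_cycles(seg))
            summed = sum_harmonic_chunks(spec, harmonic_range(1.0, 2.0),
                                         ADULT_RECIPE)
            values.append(summed.amplitude_uv[0])
        assert values[0] < values[1] < values[2]

    def test_nyquist_margin_checked(self):
        spec = _spectrum_from_row(np.ones(40))
        with pytest.raises(ValueError):
            sum_harmonic_chunks(spec, HarmonicSet(1.0, [1]), ADULT_RECIPE)
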