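"""Pre-processing stages against independent oracles and stated
invariants."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from peakconcord import (
    ConfigError,
    DataError,
    align_fft,
    average_spectrum,
    detect_peaks,
    estimate_baseline,
    normalize,
    quantify,
    run_preset,
    smooth,
    subtract_baseline,
)
from peakconcord.preprocess import (
    PRESET_DEFAULT_SNR,
    fft_shift_offset,
    rescale_min_zero,
)
from peakconcord.simulate import SimulationConfig, simulate_dataset

from conftest import make_spectrum


class TestSmooth:
    def test_savitzky_golay_exact_on_polynomial(self):
        mz = np.linspace(1000.0, 2000.0, 201)
        y = (mz / 1000.0) ** 2
        out = smooth(make_spectrum(mz, y), "savitzky_golay",
                     window_length=11, polyorder=2)
        assert np.allclose(out.intensity[5:-5], y[5:-5], rtol=1e-10)

    def test_udwt_zero_threshold_is_identity(self, gaussian_spectrum):
        noisy = gaussian_spectrum.with_intensity(
            gaussian_spectrum.intensity
            + np.random.default_rng(0).normal(0, 1, len(gaussian_spectrum))
        )
        out = smooth(noisy, "udwt", threshold_scale=0.0)
        assert np.allclose(out.intensity, noisy.intensity, atol=1e-8)

    def test_savitzky_golay_matches_direct_convolution_on_step(self):
        """On a 20-point step function the filter output equals the
        explicit least-squares convolution computed position by position."""
        mz = np.arange(20, dtype=float) + 1000.0
        y = np.where(np.arange(20) < 10, 0.0, 10.0)
        window, order = 7, 2
        out = smooth(make_spectrum(mz, y), "savitzky_golay",
                     window_length=window, polyorder=order)
        coeffs = savgol_coeffs(window, order)[::-1]
        half = window // 2
        expected = np.array(
            [np.dot(coeffs, y[i - half : i + half + 1])
             for i in range(half, 20 - half)]
        )
        assert np.allclose(out.intensity[half:-half], expected)
        assert not np.allclose(out.intensity, y)  # deviates near the step

    def test_window_longer_than_spectrum_rejected(self):
        s = make_spectrum([1.0, 2.0, 3.0], [0.0, 1.0, 0.0])
        with pytest.raises(ConfigError):
            smooth(s, "savitzky_golay", window_length=11)


class TestBaselines:
    def test_monotone_minimum_of_decreasing_spectrum_is_itself(self):
        mz = np.linspace(1000, 2000, 50)
        y = np.exp(-mz / 500.0)
        s = make_spectrum(mz, y)
        base = estimate_baseline(s, "monotone_minimum")
        assert np.array_equal(base, y)
        assert np.allclose(subtract_baseline(s, base).intensity, 0.0)

    @pytest.mark.parametrize(
        "method", ["restrained_moving_average", "monotone_minimum", "linear_interpolation"]
    )
    def test_flat_spectrum_baseline_is_the_constant(self, method):
        s = make_spectrum(np.linspace(1000, 2000, 100), np.full(100, 7.5))
        base = estimate_baseline(s, method)
        assert np.allclose(base, 7.5)

    def test_monotone_minimum_matches_running_min_recursion(self):
        """Exp decay plus one Gaussian bump, checked against a hand-run
        of b[i] = min(b[i-1], y[i]) on 30 points."""
        mz = np.linspace(1000.0, 2000.0, 30)
        y = 10 * np.exp(-mz / 800.0) + 5 * np.exp(-((mz - 1500) ** 2) / (2 * 60**2))
        s = make_spectrum(mz, y)
        base = estimate_baseline(s, "monotone_minimum")
        expected = np.empty_like(y)
        expected[0] = y[0]
        for i in range(1, 30):
            expected[i] = min(expected[i - 1], y[i])
        assert np.array_equal(base, expected)
        apex = np.argmax(y - base)
        assert base[apex] == np.min(y[:apex + 1])  # pre-peak minimum

    @pytest.mark.parametrize(
        "method", ["restrained_moving_average", "monotone_minimum", "linear_interpolation"]
    )
    def test_baseline_never_exceeds_signal(self, method, gaussian_spectrum):
        noisy = gaussian_spectrum.with_intensity(
            gaussian_spectrum.intensity
            + 20 * np.exp(-gaussian_spectrum.mz / 700.0)
        )
        base = estimate_baseline(noisy, method)
        assert np.all(base <= noisy.intensity + 1e-12)

    def test_subtraction_clips_to_non_negative(self, gaussian_spectrum):
        out = subtract_baseline(gaussian_spectrum, np.full(len(gaussian_spectrum), 5.0))
        assert out.intensity.min() >= 0.0
        assert rescale_min_zero(out).intensity.min() == 0.0


class TestNormalize:
    def test_tic_scales_to_mean_total(self):
        mz = np.linspace(1000, 2000, 11)
        s1 = make_spectrum(mz, np.full(11, 10 / 11))
        s2 = make_spectrum(mz, np.full(11, 30 / 11))
        out = normalize([s1, s2], "tic")
        assert out[0].intensity.sum() == pytest.approx(20.0)
        assert out[1].intensity.sum() == pytest.approx(20.0)
        assert np.allclose(out[0].intensity / s1.intensity, 2.0)
        assert np.allclose(out[1].intensity / s2.intensity, 2 / 3)

    def test_single_spectrum_unchanged(self, gaussian_spectrum):
        for method in ("tic", "median_auc"):
            out = normalize([gaussian_spectrum], method)
            assert np.allclose(out[0].intensity, gaussian_spectrum.intensity)

    def test_median_auc_equalizes_trapezoid_areas(self):
        mz = np.linspace(0.0, 2.0, 21)
        spectra = [make_spectrum(mz + 1000, np.full(21, a / 2.0)) for a in (5.0, 7.0, 100.0)]
        out = normalize(spectra, "median_auc")
        areas = [np.trapezoid(s.intensity, s.mz) for s in out]
        assert np.allclose(areas, 7.0)
        factors = [o.intensity[0] / s.intensity[0] for o, s in zip(out, spectra)]
        assert np.allclose(factors, [1.4, 1.0, 0.07])

    def test_zero_intensity_spectrum_named_in_error(self):
        mz = np.linspace(1000, 2000, 5)
        bad = make_spectrum(mz, np.zeros(5), sample_id="S7")
        good = make_spectrum(mz, np.ones(5))
        with pytest.raises(DataError, match="S7"):
            normalize([good, bad], "tic")

    def test_tic_sums_equal_to_tight_tolerance(self, small_dataset):
        spectra, _ = small_dataset
        out = normalize(list(spectra), "tic")
        sums = np.array([s.intensity.sum() for s in out])
        assert np.allclose(sums, sums[0], rtol=1e-9)


class TestAverageAndAlign:
    def test_average_identity_and_symmetry(self, gaussian_spectrum):
        assert np.array_equal(
            average_spectrum([gaussian_spectrum]).intensity,
            gaussian_spectrum.intensity,
        )
        mirrored = gaussian_spectrum.with_intensity(-gaussian_spectrum.intensity + 8.0)
        avg = average_spectrum([gaussian_spectrum, mirrored])
        assert np.allclose(avg.intensity, 4.0)

    def test_average_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        mz = np.linspace(1000, 2000, 64)
        spectra = [make_spectrum(mz, rng.normal(10, 2, 64)) for _ in range(10)]
        avg = average_spectrum(spectra)
        expected = np.zeros(64)
        for i in range(64):
            for s in spectra:
                expected[i] += s.intensity[i]
        expected /= 10
        assert np.allclose(avg.intensity, expected)

    def test_mismatched_grids_rejected(self, gaussian_spectrum):
        other = make_spectrum(gaussian_spectrum.mz + 1.0, gaussian_spectrum.intensity)
        with pytest.raises(DataError):
            average_spectrum([gaussian_spectrum, other])

    def test_identical_spectrum_has_zero_offset(self, gaussian_spectrum):
        assert fft_shift_offset(
            gaussian_spectrum.intensity, gaussian_spectrum.intensity, 10
        ) == 0

    def test_constructed_shift_recovered(self, gaussian_spectrum):
        y = gaussian_spectrum.intensity
        shifted = np.concatenate([np.full(3, y[0]), y[:-3]])  # right by 3
        s = gaussian_spectrum.with_intensity(shifted)
        assert fft_shift_offset(shifted, y, 10) == -3
        aligned = align_fft([s], gaussian_spectrum, max_shift=10)[0]
        assert np.allclose(aligned.intensity[3:-3], y[3:-3])

    def test_noisy_shift_recovery_against_brute_force(self, gaussian_spectrum):
        """Offset recovery on noisy shifted Gaussians agrees with an
        explicit argmax over all allowed integer lags, and recovers the
        planted shift in >= 95% of trials."""
        y = gaussian_spectrum.intensity
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(100):
            shifted = np.concatenate([np.full(5, y[0]), y[:-5]])
            noisy = shifted + rng.normal(0, 0.05 * y.max(), y.size)
            got = fft_shift_offset(noisy, y, 10)
            brute = max(
                range(-10, 11),
                key=lambda k: float(np.dot(np.roll(noisy, k), y)),
            )
            assert got == brute
            hits += got == -5
        assert hits >= 95

    def test_max_shift_must_be_smaller_than_length(self, gaussian_spectrum):
        with pytest.raises(ConfigError):
            align_fft([gaussian_spectrum], gaussian_spectrum,
                      max_shift=len(gaussian_spectrum))


def scan_oracle(y, noise, snr):
    """Exhaustive grid scan: every point tested for the local-maximum
    plateau rule and the SNR condition."""
    peaks = []
    for i in range(1, y.size - 1):
        if y[i] > y[i - 1] and y[i] >= y[i + 1] and y[i] / noise >= snr:
            peaks.append(i)
    return np.array(peaks, dtype=int)


class TestDetectPeaks:
    def test_single_gaussian_single_peak(self, gaussian_spectrum):
        peak_mz, intervals = detect_peaks(
            gaussian_spectrum, "local_maxima", snr_threshold=3.0, noise=1.0
        )
        assert peak_mz.size == 1
        assert peak_mz[0] == pytest.approx(1500.0, abs=1.0)
        assert len(intervals) == 1

    def test_flat_spectrum_no_peaks(self):
        s = make_spectrum(np.linspace(1000, 2000, 100), np.full(100, 2.0))
        peak_mz, intervals = detect_peaks(s, "local_maxima", 1.0, noise=1.0)
        assert peak_mz.size == 0 and intervals == []

    def test_counts_non_increasing_and_match_scan_oracle(self):
        mz = np.linspace(1000.0, 2000.0, 800)
        rng = np.random.default_rng(21)
        y = (
            10 * np.exp(-((mz - 1300) ** 2) / (2 * 15**2))
            + 3 * np.exp(-((mz - 1700) ** 2) / (2 * 15**2))
            + rng.normal(0, 1, mz.size)
        )
        y = np.clip(y, 0, None)
        s = make_spectrum(mz, y)
        counts = []
        for snr in (2.5, 5.0, 8.0):
            peak_mz, _ = detect_peaks(s, "local_maxima", snr, noise=1.0)
            oracle = scan_oracle(y, 1.0, snr)
            assert np.array_equal(peak_mz, mz[oracle])
            counts.append(peak_mz.size)
        assert counts[0] >= counts[1] >= counts[2]

    def test_oracle_agreement_on_random_signals(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(50, 1000))
            mz = np.linspace(1000, 3000, n)
            y = np.abs(rng.normal(2, 1, n))
            snr = float(rng.uniform(0.5, 4))
            peak_mz, intervals = detect_peaks(
                make_spectrum(mz, y), "local_maxima", snr, noise=1.0
            )
            oracle = scan_oracle(y, 1.0, snr)
            assert np.array_equal(peak_mz, mz[oracle])
            # every peak strictly inside its interval; intervals ordered
            for p, (a, b) in zip(oracle, intervals):
                assert a <= p < b
            for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
                assert b1 <= a2

    def test_cwt_finds_isolated_gaussians(self):
        mz = np.linspace(1000.0, 3000.0, 2000)
        y = 30 * np.exp(-((mz - 1500) ** 2) / (2 * 12**2)) + 20 * np.exp(
            -((mz - 2400) ** 2) / (2 * 18**2)
        )
        peak_mz, _ = detect_peaks(make_spectrum(mz, y), "cwt", 3.0, noise=1.0)
        assert peak_mz.size == 2
        assert np.allclose(peak_mz, [1500.0, 2400.0], atol=5.0)

    def test_nonpositive_snr_rejected(self, gaussian_spectrum):
        with pytest.raises(ConfigError):
            detect_peaks(gaussian_spectrum, "local_maxima", 0.0)


class TestQuantify:
    def test_average_spectrum_row_reproduces_apexes(self, gaussian_spectrum):
        peak_mz, intervals = detect_peaks(gaussian_spectrum, "local_maxima", 1.0, noise=1.0)
        profile = quantify([gaussian_spectrum], intervals, peak_mz)
        assert profile.intensity_matrix[0, 0] == gaussian_spectrum.intensity.max()

    def test_zero_spectrum_gives_zero_row(self, gaussian_spectrum):
        zero = gaussian_spectrum.with_intensity(np.zeros(len(gaussian_spectrum)))
        profile = quantify([zero], [(10, 50), (100, 200)], np.array([1010.0, 1100.0]))
        assert np.all(profile.intensity_matrix == 0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(17)
        mz = np.linspace(1000, 2000, 300)
        spectra = [make_spectrum(mz, np.abs(rng.normal(5, 2, 300))) for _ in range(5)]
        intervals = [(0, 60), (80, 150), (150, 220), (260, 300)]
        peak_mz = np.array([mz[30], mz[100], mz[180], mz[280]])
        profile = quantify(spectra, intervals, peak_mz)
        for i, s in enumerate(spectra):
            for j, (a, b) in enumerate(intervals):
                expected = max(s.intensity[k] for k in range(a, b))
                assert profile.intensity_matrix[i, j] == expected

    def test_interval_outside_grid_rejected(self, gaussian_spectrum):
        with pytest.raises(DataError):
            quantify([gaussian_spectrum], [(0, 10**6)], np.array([1500.0]))


class TestRunPreset:
    def test_default_snr_thresholds(self):
        assert PRESET_DEFAULT_SNR == {
            "specalign_like": 1.5,
            "mswpro_like": 3.0,
            "cromwell_like": 5.0,
        }

    def test_unknown_preset_error_lists_valid_names(self, small_dataset):
        spectra, _ = small_dataset
        with pytest.raises(ConfigError, match="cromwell_like"):
            run_preset(spectra, "nope")

    def test_noise_free_single_peak_all_presets_agree(self):
        cfg = SimulationConfig(
            n_cancer=2, n_normal=2, mz_range=(1000.0, 2000.0), n_peaks=1,
            de_fraction=0.0, fold_changes=(), baseline_amplitude=0.0,
            noise_sd=0.0, scale_sd=0.0, mz_jitter_sd=0.0, biological_cv=0.0,
            seed=5,
        )
        spectra, truth = simulate_dataset(cfg)
        found = {}
        for preset in PRESET_DEFAULT_SNR:
            profile = run_preset(spectra, preset)
            assert profile.n_peaks == 1
            found[preset] = profile.peak_mz[0]
        for mz in found.values():
            assert abs(mz - truth.true_mz[0]) <= 0.003 * truth.true_mz[0]

    def test_peak_counts_non_increasing_in_snr(self, small_dataset):
        spectra, _ = small_dataset
        for preset in PRESET_DEFAULT_SNR:
            counts = [
                run_preset(spectra, preset, snr).n_peaks
                for snr in (1.5, 5.0, 40.0, 200.0)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_profile_rows_cover_all_spectra_and_are_non_negative(self, small_dataset):
        spectra, _ = small_dataset
        profile = run_preset(spectra, "cromwell_like")
        assert profile.n_rows == len(spectra)
        assert np.all(profile.intensity_matrix >= 0)

    def test_low_snr_cromwell_contains_default_specalign(self):
        """Threshold ordering: the permissive wide profile holds every
        peak of the conservative one in >= 90% of seeds."""
        from peakconcord import match_peaks

        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_cancer=4, n_normal=3, mz_range=(1000.0, 4000.0),
                n_peaks=10, de_fraction=0.2, fold_changes=(2.0, 0.5),
                seed=seed,
            )
            spectra, _ = simulate_dataset(cfg)
            wide = run_preset(spectra, "cromwell_like", 2.0)
            narrow = run_preset(spectra, "specalign_like", 1.5)
            m = match_peaks(narrow.peak_mz, wide.peak_mz, 0.003)
            hits += m.k == narrow.n_peaks
        assert hits >= 18
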