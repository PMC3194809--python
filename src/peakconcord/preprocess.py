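"""Average-spectrum-dependent pre-processing.

All three supported procedures share one skeleton: smooth, subtract a
baseline, normalize, form the average spectrum of the whole dataset,
detect peaks once on that average, then quantify each detected peak in
every individual spectrum by the maximum intensity inside the peak's
interval. They differ in the method used at each slot:

``specalign_like``
    Savitzky-Golay smoothing; restrained-moving-average baseline;
    rescale so the minimum is 0; total-ion-current normalization; FFT
    alignment of each spectrum to the average; local-maxima picking with
    a height-ratio SNR (default threshold 1.5).
``mswpro_like``
    Peak detection by continuous-wavelet-transform ridge lines on the
    average spectrum (default SNR 3); per-spectrum quantification after
    linear-interpolation baseline subtraction and median-AUC
    normalization.
``cromwell_like``
    Undecimated-discrete-wavelet-transform denoising; monotone-minimum
    baseline; average-TIC normalization; local-maxima picking on the
    denoised average (default SNR 5).

SNR conventions: the noise scale is 1.4826 x the median absolute
deviation of either the finest-level UDWT detail coefficients
(``cromwell_like`` and the CWT picker) or of the residual left after
Savitzky-Golay smoothing (the ``specalign_like`` "height ratio"); a
peak's SNR is its baseline-subtracted apex divided by that scale.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .errors import ConfigError, DataError
from .profiles import PeakProfile
from .spectra import Spectrum, SpectrumSet

__all__ = [
    "smooth",
    "estimate_baseline",
    "subtract_baseline",
    "rescale_min_zero",
    "normalize",
    "average_spectrum",
    "align_fft",
    "fft_shift_offset",
    "detect_peaks",
    "quantify",
    "run_preset",
    "noise_scale_udwt",
    "noise_scale_residual",
    "PRESET_DEFAULT_SNR",
]

# default detection thresholds of the three procedures
PRESET_DEFAULT_SNR = {
    "specalign_like": 1.5,
    "mswpro_like": 3.0,
    "cromwell_like": 5.0,
}

_NOISE_FLOOR = 1e-12


# --------------------------------------------------------------- smoothing
def _udwt_denoise(
    y: np.ndarray,
    wavelet: str = "db8",
    level: int | None = None,
    threshold_scale: float = 3.0,
) -> np.ndarray:
    """Hard-threshold the detail coefficients of a stationary (undecimated)
    wavelet transform. ``threshold_scale = 0`` reproduces the input exactly
    (perfect reconstruction)."""
    n = y.size
    max_level = int(np.log2(n)) if n > 1 else 1
    if level is None:
        level = min(5, max_level)
    if level > max_level:
        raise ConfigError(
            f"decomposition level {level} exceeds log2(length)={max_level}"
        )
    block = 2**level
    pad = (-n) % block
    ypad = np.pad(y, (0, pad), mode="edge")
    coeffs = pywt.swt(ypad, wavelet, level=level, norm=False)
    if threshold_scale > 0:
        finest_detail = coeffs[-1][1]
        sigma = 1.4826 * np.median(np.abs(finest_detail - np.median(finest_detail)))
        thr = threshold_scale * sigma
        coeffs = [
            (ca, pywt.threshold(cd, thr, mode="hard")) for ca, cd in coeffs
        ]
    out = pywt.iswt(coeffs, wavelet, norm=False)
    return np.asarray(out[:n], dtype=float)


def smooth(spectrum: Spectrum, method: str = "savitzky_golay", **params) -> Spectrum:
    """Smooth a spectrum in place of its intensity array.

    ``savitzky_golay`` takes ``window_length`` (odd, default 11) and
    ``polyorder`` (default 3); ``udwt`` takes ``wavelet`` (default
    ``db8``), ``level`` and ``threshold_scale`` (default 3.0 noise
    sigmas, hard threshold).
    """
    y = spectrum.intensity
    if method == "savitzky_golay":
        window = int(params.get("window_length", 11))
        polyorder = int(params.get("polyorder", 3))
        if window > y.size:
            raise ConfigError(
                f"window_length {window} longer than spectrum ({y.size})"
            )
        if window % 2 == 0 or window <= polyorder:
            raise ConfigError("window_length must be odd and > polyorder")
        out = signal.savgol_filter(y, window, polyorder)
    elif method == "udwt":
        out = _udwt_denoise(
            y,
            wavelet=params.get("wavelet", "db8"),
            level=params.get("level"),
            threshold_scale=params.get("threshold_scale", 3.0),
        )
    else:
        raise ConfigError(
            f"unknown smoothing method {method!r}; use savitzky_golay or udwt"
        )
    if np.any(~np.isfinite(out)):
        raise DataError("smoothing produced non-finite values")
    return spectrum.with_intensity(out)


# --------------------------------------------------------------- noise scales
def noise_scale_udwt(y: np.ndarray, wavelet: str = "db8") -> float:
    """1.4826 x MAD of the finest-level UDWT detail coefficients."""
    n = np.asarray(y).size
    pad = (-n) % 2
    ypad = np.pad(np.asarray(y, dtype=float), (0, pad), mode="edge")
    (_, detail), = pywt.swt(ypad, wavelet, level=1, norm=False)
    mad = np.median(np.abs(detail - np.median(detail)))
    return max(1.4826 * float(mad), _NOISE_FLOOR)


def noise_scale_residual(
    y: np.ndarray, window_length: int = 11, polyorder: int = 3
) -> float:
    """1.4826 x MAD of the residual after Savitzky-Golay smoothing."""
    y = np.asarray(y, dtype=float)
    resid = y - signal.savgol_filter(y, min(window_length, y.size - (y.size + 1) % 2), polyorder)
    mad = np.median(np.abs(resid - np.median(resid)))
    return max(1.4826 * float(mad), _NOISE_FLOOR)


# --------------------------------------------------------------- baselines
def estimate_baseline(
    spectrum: Spectrum, method: str = "monotone_minimum", **params
) -> np.ndarray:
    """Estimate the slowly varying background under a spectrum.

    ``restrained_moving_average``
        moving average (window = ``window_frac`` of the grid, default 2%)
        of a running local minimum, restrained to stay at or below the
        signal pointwise.
    ``monotone_minimum``
        left-to-right running minimum (non-increasing by construction).
    ``linear_interpolation``
        linear interpolation between the local minima of ``n_segments``
        (default 20) equal-width segments.
    """
    y = spectrum.intensity
    if y.size == 0:
        raise DataError("empty spectrum")
    if method == "monotone_minimum":
        return np.minimum.accumulate(y)
    if method == "restrained_moving_average":
        frac = float(params.get("window_frac", 0.02))
        n_iter = int(params.get("n_iter", 4))
        w = max(3, int(round(frac * y.size)))
        # moving average restrained to stay at or below the signal,
        # iterated so peak regions are progressively suppressed while
        # flat background keeps its level (no min-filter undershoot)
        base = y.copy()
        for _ in range(n_iter):
            base = np.minimum(uniform_filter1d(base, size=w), y)
        return base
    if method == "linear_interpolation":
        n_segments = int(params.get("n_segments", 20))
        edges = np.linspace(0, y.size, n_segments + 1).astype(int)
        anchors_x, anchors_y = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            if b > a:
                i = a + int(np.argmin(y[a:b]))
                anchors_x.append(spectrum.mz[i])
                anchors_y.append(y[i])
        base = np.interp(spectrum.mz, anchors_x, anchors_y)
        return np.minimum(base, y)
    raise ConfigError(
        f"unknown baseline method {method!r}; use restrained_moving_average, "
        "monotone_minimum or linear_interpolation"
    )


def subtract_baseline(spectrum: Spectrum, baseline: np.ndarray) -> Spectrum:
    """Subtract a baseline and clip at zero."""
    return spectrum.with_intensity(np.clip(spectrum.intensity - baseline, 0.0, None))


def rescale_min_zero(spectrum: Spectrum) -> Spectrum:
    """Shift intensities so the minimum is exactly 0."""
    return spectrum.with_intensity(spectrum.intensity - spectrum.intensity.min())


# --------------------------------------------------------------- normalization
def normalize(spectra: list[Spectrum], method: str = "tic") -> list[Spectrum]:
    """Scale each spectrum by one positive factor.

    ``tic`` equalizes intensity sums to the mean pre-normalization sum
    (same total ion current); ``median_auc`` equalizes trapezoidal areas
    to the median pre-normalization area.
    """
    if not spectra:
        raise DataError("normalize needs at least one spectrum")
    if method == "tic":
        sizes = np.array([s.intensity.sum() for s in spectra])
        target = sizes.mean()
    elif method == "median_auc":
        sizes = np.array(
            [np.trapezoid(s.intensity, s.mz) for s in spectra]
        )
        target = np.median(sizes)
    else:
        raise ConfigError(f"unknown normalization method {method!r}")
    for s, v in zip(spectra, sizes):
        if v <= 0:
            raise DataError(
                f"spectrum {s.label} has non-positive total intensity; "
                "cannot normalize"
            )
    return [s.with_intensity(s.intensity * (target / v)) for s, v in zip(spectra, sizes)]


# --------------------------------------------------------------- averaging
def average_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean intensity over spectra sharing one m/z grid."""
    if not spectra:
        raise DataError("average_spectrum needs at least one spectrum")
    grid = spectra[0].mz
    for s in spectra[1:]:
        if s.mz.size != grid.size or not np.array_equal(s.mz, grid):
            raise DataError(
                f"spectrum {s.label} is on a different m/z grid; no implicit "
                "resampling is performed"
            )
    mean = np.mean([s.intensity for s in spectra], axis=0)
    return Spectrum(grid, mean, sample_id="<average>", replicate_id=-1, group="")


# --------------------------------------------------------------- alignment
def fft_shift_offset(y: np.ndarray, reference: np.ndarray, max_shift: int) -> int:
    """Integer grid offset (|offset| <= max_shift) to apply to ``y`` that
    maximizes its circular cross-correlation with ``reference``."""
    n = y.size
    if max_shift >= n:
        raise ConfigError("max_shift must be smaller than the spectrum length")
    corr = np.fft.ifft(np.fft.fft(reference) * np.conj(np.fft.fft(y))).real
    lags = np.arange(-max_shift, max_shift + 1)
    values = corr[lags % n]
    return int(lags[np.argmax(values)])


def _shift_with_edge_pad(y: np.ndarray, k: int) -> np.ndarray:
    if k == 0:
        return y.copy()
    out = np.empty_like(y)
    if k > 0:
        out[k:] = y[:-k]
        out[:k] = y[0]
    else:
        out[:k] = y[-k:]
        out[k:] = y[-1]
    return out


def align_fft(
    spectra: list[Spectrum], reference: Spectrum, max_shift: int = 10
) -> list[Spectrum]:
    """Shift each spectrum by the integer offset maximizing its
    cross-correlation with the reference; edges are padded with the edge
    value."""
    out = []
    for s in spectra:
        if s.mz.size != reference.mz.size:
            raise DataError("alignment requires a common grid")
        k = fft_shift_offset(s.intensity, reference.intensity, max_shift)
        out.append(s.with_intensity(_shift_with_edge_pad(s.intensity, k)))
    return out


# --------------------------------------------------------------- detection
def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateau ties resolve to the lowest
    index (y[i] > y[i-1] and y[i] >= y[i+1]); grid edges excluded."""
    interior = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    return np.flatnonzero(interior) + 1


def _local_minima_boundaries(y: np.ndarray) -> np.ndarray:
    """Candidate interval boundaries: local minima (plateau rule mirrored)
    plus both grid ends."""
    interior = (y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])
    return np.concatenate(([0], np.flatnonzero(interior) + 1, [y.size]))


def _intervals_for(peaks: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    bounds = _local_minima_boundaries(y)
    intervals = []
    for p in peaks:
        left = bounds[np.searchsorted(bounds, p, side="right") - 1]
        right = bounds[np.searchsorted(bounds, p, side="right")]
        intervals.append((int(left), int(right)))
    return intervals


def detect_peaks(
    avg: Spectrum,
    method: str = "local_maxima",
    snr_threshold: float = 3.0,
    noise: float | None = None,
    cwt_widths: np.ndarray | None = None,
    cwt_min_length: int = 6,
    cwt_gap_thresh: int = 2,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Detect peaks on a smoothed, baseline-subtracted average spectrum.

    Returns peak m/z values (sorted) and per-peak half-open index
    intervals bounded by the flanking local minima. ``local_maxima``
    keeps every strict local maximum whose apex / noise ratio reaches
    ``snr_threshold``; ``cwt`` traces Mexican-hat ridge lines across 12
    dyadically spaced scales (minimum ridge length 6, gap tolerance 2)
    and applies the same SNR filter at the ridge apexes.
    """
    if snr_threshold <= 0:
        raise ConfigError("snr_threshold must be positive")
    y = avg.intensity
    if noise is None:
        noise = noise_scale_udwt(y)
    # dynamic-range floor: on effectively noise-free data the estimated
    # noise vanishes and numerical ripple would otherwise pass any SNR
    noise = max(noise, 1e-4 * float(np.max(y, initial=0.0)), _NOISE_FLOOR)
    if method == "local_maxima":
        peaks = _local_maxima(y)
    elif method == "cwt":
        if cwt_widths is None:
            cwt_widths = np.geomspace(1.0, 64.0, 12)
        peaks = np.asarray(
            signal.find_peaks_cwt(
                y,
                widths=cwt_widths,
                gap_thresh=cwt_gap_thresh,
                min_length=cwt_min_length,
                min_snr=0.0,
            ),
            dtype=int,
        )
        # snap ridge apexes to the nearest local maximum of the signal
        if peaks.size:
            maxima = _local_maxima(y)
            if maxima.size:
                peaks = np.unique(
                    maxima[np.argmin(np.abs(maxima[None, :] - peaks[:, None]), axis=1)]
                )
            else:
                peaks = np.array([], dtype=int)
    else:
        raise ConfigError(
            f"unknown detection method {method!r}; use local_maxima or cwt"
        )
    if peaks.size:
        keep = y[peaks] / noise >= snr_threshold
        peaks = peaks[keep]
    return avg.mz[peaks], _intervals_for(peaks, y)


# --------------------------------------------------------------- quantification
def quantify(
    spectra: list[Spectrum],
    intervals: list[tuple[int, int]],
    peak_mz: np.ndarray,
    preset: str = "",
    snr_threshold: float = float("nan"),
) -> PeakProfile:
    """Per-spectrum peak intensities: the maximum inside each detection
    interval, one profile row per input spectrum."""
    peak_mz = np.asarray(peak_mz, dtype=float)
    if not spectra:
        raise DataError("quantify needs at least one spectrum")
    n = spectra[0].mz.size
    for a, b in intervals:
        if not (0 <= a < b <= n):
            raise DataError(f"interval [{a}, {b}) outside the grid (length {n})")
    matrix = np.empty((len(spectra), len(intervals)))
    for i, s in enumerate(spectra):
        if s.mz.size != n:
            raise DataError("all spectra must share the detection grid")
        for j, (a, b) in enumerate(intervals):
            matrix[i, j] = s.intensity[a:b].max()
    return PeakProfile(
        peak_mz=peak_mz,
        intervals=intervals,
        intensity_matrix=matrix,
        sample_ids=[s.sample_id for s in spectra],
        replicate_ids=[s.replicate_id for s in spectra],
        groups=[s.group for s in spectra],
        preset=preset,
        snr_threshold=snr_threshold,
        mz_grid=spectra[0].mz,
    )


# --------------------------------------------------------------- presets
def _run_specalign(spectra: list[Spectrum], snr: float, p: dict) -> PeakProfile:
    window = p.get("window_length", 11)
    polyorder = p.get("polyorder", 3)
    smoothed = [
        smooth(s, "savitzky_golay", window_length=window, polyorder=polyorder)
        for s in spectra
    ]
    debased = [
        rescale_min_zero(
            subtract_baseline(
                s,
                estimate_baseline(
                    s, "restrained_moving_average",
                    window_frac=p.get("window_frac", 0.02),
                ),
            )
        )
        for s in smoothed
    ]
    normed = normalize(debased, "tic")
    avg = average_spectrum(normed)
    aligned = align_fft(normed, avg, max_shift=p.get("max_shift", 10))
    avg = average_spectrum(aligned)
    # height-ratio noise: per-spectrum Savitzky-Golay residual scale,
    # averaged over spectra (estimated before smoothing removed it)
    noise = float(
        np.mean([noise_scale_residual(s.intensity, window, polyorder) for s in spectra])
    )
    peak_mz, intervals = detect_peaks(
        avg, "local_maxima", snr_threshold=snr, noise=noise
    )
    return quantify(aligned, intervals, peak_mz, "specalign_like", snr)


def _run_mswpro(spectra: list[Spectrum], snr: float, p: dict) -> PeakProfile:
    avg_raw = average_spectrum(spectra)
    # detection signal: lightly smoothed, baseline-free average
    avg_det = subtract_baseline(
        avg_raw, estimate_baseline(avg_raw, "linear_interpolation",
                                   n_segments=p.get("n_segments", 20))
    )
    avg_det = smooth(
        avg_det, "savitzky_golay",
        window_length=p.get("window_length", 11),
        polyorder=p.get("polyorder", 3),
    )
    noise = noise_scale_udwt(avg_raw.intensity)
    peak_mz, intervals = detect_peaks(
        avg_det, "cwt", snr_threshold=snr, noise=noise
    )
    debased = [
        subtract_baseline(
            s,
            estimate_baseline(
                s, "linear_interpolation", n_segments=p.get("n_segments", 20)
            ),
        )
        for s in spectra
    ]
    normed = normalize(debased, "median_auc")
    return quantify(normed, intervals, peak_mz, "mswpro_like", snr)


def _run_cromwell(spectra: list[Spectrum], snr: float, p: dict) -> PeakProfile:
    wavelet = p.get("wavelet", "db8")
    thr = p.get("threshold_scale", 3.0)
    avg_raw = average_spectrum(spectra)
    noise = noise_scale_udwt(avg_raw.intensity, wavelet)
    avg = smooth(avg_raw, "udwt", wavelet=wavelet, threshold_scale=thr)
    avg = subtract_baseline(avg, estimate_baseline(avg, "monotone_minimum"))
    peak_mz, intervals = detect_peaks(
        avg, "local_maxima", snr_threshold=snr, noise=noise
    )
    processed = [
        subtract_baseline(
            d, estimate_baseline(d, "monotone_minimum")
        )
        for d in (
            smooth(s, "udwt", wavelet=wavelet, threshold_scale=thr)
            for s in spectra
        )
    ]
    normed = normalize(processed, "tic")
    return quantify(normed, intervals, peak_mz, "cromwell_like", snr)


_PRESETS = {
    "specalign_like": _run_specalign,
    "mswpro_like": _run_mswpro,
    "cromwell_like": _run_cromwell,
}


def run_preset(
    spectra: SpectrumSet | list[Spectrum],
    preset: str,
    snr_threshold: float | None = None,
    **params,
) -> PeakProfile:
    """Run one complete pre-processing procedure.

    Peaks are detected once on the dataset's average spectrum and
    quantified in every individual spectrum (one profile row per input
    spectrum, technical replicates included). ``snr_threshold`` defaults
    to the procedure's conventional value (1.5 / 3 / 5).
    """
    if preset not in _PRESETS:
        raise ConfigError(
            f"unknown preset {preset!r}; valid presets: {sorted(_PRESETS)}"
        )
    spectra = list(spectra)
    if len(spectra) < 2:
        raise DataError("run_preset needs at least 2 spectra")
    if snr_threshold is None:
        snr_threshold = PRESET_DEFAULT_SNR[preset]
    return _PRESETS[preset](spectra, float(snr_threshold), params)
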