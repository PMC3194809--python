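"""Synthetic SELDI-TOF spectrum sets with known ground truth.

Each biological sample contributes ``n_replicates`` technical spectra on
a common m/z grid. A spectrum is built as

    scale * (sum of Gaussian peaks + exponential baseline) + noise

where the Gaussian peak width grows linearly with m/z (sigma = a + b*mz),
the baseline is A*exp(-mz/tau), ``scale`` is a per-spectrum log-normal
factor (technical intensity variation that TIC normalization should
remove), and the additive noise is white Gaussian. A per-spectrum
constant m/z jitter shifts every peak centre before gridding, giving the
FFT alignment step a recoverable signal. True peak heights are drawn
once per sample (log-normal biological variation around the group mean),
so the two replicates of a sample agree before technical noise — the
property the duplicate-consensus step exploits.

A designated subset of peaks is differentially expressed: the cancer
group mean is the normal mean times a configured fold change.

The module also provides an abstract p-value mixture generator used to
exercise the simple and stratified FDR procedures without spectra, and
an evaluator that scores a detected peak list against the ground truth
(sensitivity and empirical FDR under a relative m/z matching window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .matching import match_peaks
from .spectra import Spectrum, SpectrumSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "simulate_pvalue_mixture",
    "evaluate_detection",
]


@dataclass
class SimulationConfig:
    """Study-condition knobs for the spectrum simulator.

    Defaults describe a desk-scale two-group cohort (30 cancer vs 15
    normal samples in duplicate, echoing a 2:1 case/control design) over
    the 1–10 kDa window with 30 resolvable peaks, one fifth of them
    differentially expressed at a two-fold change.
    """

    n_cancer: int = 30
    n_normal: int = 15
    n_replicates: int = 2
    mz_range: tuple[float, float] = (1000.0, 10000.0)
    grid_step: float = 1.0
    n_peaks: int = 30
    de_fraction: float = 0.2
    # balanced up/down regulation keeps the groups' total ion current
    # comparable, so TIC normalization does not smear the DE signal
    # across null peaks; a scalar applies one ratio to every DE peak
    fold_changes: float | tuple[float, ...] = (2.0, 0.5, 2.0, 0.5, 2.0, 0.5)
    peak_height_range: tuple[float, float] = (20.0, 100.0)
    peak_width_a: float = 1.0          # sigma at mz -> 0, Da
    peak_width_b: float = 0.002        # sigma slope per Da
    baseline_amplitude: float = 50.0   # intensity units at mz = 0
    baseline_decay: float = 3000.0     # Da
    noise_sd: float = 1.0
    scale_sd: float = 0.1              # sd of log per-spectrum scale
    mz_jitter_sd: float = 1.0          # Da, per-spectrum constant shift
    biological_cv: float = 0.15        # sd of log per-sample height factor
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.mz_range
        if not low < high:
            raise ConfigError("mz_range must satisfy low < high")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if min(self.peak_height_range) <= 0:
            raise ConfigError("peak heights must be positive")
        if self.peak_width_a <= 0 or self.peak_width_b < 0:
            raise ConfigError("peak width model must be positive")
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be positive")
        for name in ("noise_sd", "scale_sd", "mz_jitter_sd",
                     "baseline_amplitude", "biological_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_cancer < 1 or self.n_normal < 1 or self.n_replicates < 1:
            raise ConfigError("sample and replicate counts must be >= 1")
        if self.n_peaks < 1:
            raise ConfigError("n_peaks must be >= 1")
        # resolvability: room for all peaks at >= 2x the widest peak apart
        max_width = self.peak_width_a + self.peak_width_b * high
        if (high - low) < self.n_peaks * 2.0 * max_width:
            raise ConfigError(
                f"{self.n_peaks} peaks of width up to {max_width:.2f} Da do "
                f"not fit the m/z range with 2x-width spacing"
            )

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_peaks))

    def fold_change_vector(self) -> np.ndarray:
        fc = self.fold_changes
        if np.isscalar(fc):
            return np.full(self.n_de, float(fc))
        fc = np.asarray(fc, dtype=float)
        if fc.size != self.n_de:
            raise ConfigError(
                f"fold_changes has {fc.size} entries but {self.n_de} DE peaks"
            )
        return fc


@dataclass
class GroundTruth:
    """True peak positions and effect structure of a simulated dataset."""

    true_mz: np.ndarray                 # strictly increasing, Da
    is_de: np.ndarray                   # bool per peak
    true_fc: np.ndarray                 # cancer/normal mean ratio per peak
    group_means: pd.DataFrame           # columns: cancer, normal

    def __post_init__(self) -> None:
        self.true_mz = np.asarray(self.true_mz, dtype=float)
        self.is_de = np.asarray(self.is_de, dtype=bool)
        self.true_fc = np.asarray(self.true_fc, dtype=float)
        if not np.all(np.diff(self.true_mz) > 0):
            raise DataError("true_mz must be strictly increasing")
        if np.any(self.is_de != (np.abs(self.true_fc - 1.0) > 0)):
            raise DataError("is_de must mark exactly the peaks with fc != 1")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {
                "mz": self.true_mz,
                "is_de": self.is_de.astype(int),
                "fold_change": self.true_fc,
                "mean_cancer": self.group_means["cancer"].to_numpy(),
                "mean_normal": self.group_means["normal"].to_numpy(),
            }
        ).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruth":
        t = pd.read_csv(path, float_precision="round_trip")
        return cls(
            true_mz=t["mz"].to_numpy(),
            is_de=t["is_de"].to_numpy().astype(bool),
            true_fc=t["fold_change"].to_numpy(),
            group_means=pd.DataFrame(
                {"cancer": t["mean_cancer"], "normal": t["mean_normal"]}
            ),
        )


def _draw_peak_positions(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    low, high = cfg.mz_range
    max_width = cfg.peak_width_a + cfg.peak_width_b * high
    min_gap = 2.0 * max_width
    margin = 3.0 * max_width  # keep apexes clear of the grid edges
    for _ in range(1000):
        pos = np.sort(rng.uniform(low + margin, high - margin, size=cfg.n_peaks))
        if cfg.n_peaks == 1 or np.min(np.diff(pos)) >= min_gap:
            return pos
    raise ConfigError(
        "could not place resolvable peaks; lower n_peaks or peak widths"
    )


def simulate_dataset(config: SimulationConfig) -> tuple[SpectrumSet, GroundTruth]:
    """Simulate a duplicate-spectrum two-group dataset with known truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    low, high = cfg.mz_range
    grid = np.arange(low, high + cfg.grid_step / 2, cfg.grid_step)

    centers = _draw_peak_positions(cfg, rng)
    sigmas = cfg.peak_width_a + cfg.peak_width_b * centers
    h_lo, h_hi = cfg.peak_height_range
    normal_means = rng.uniform(h_lo, h_hi, size=cfg.n_peaks)

    is_de = np.zeros(cfg.n_peaks, dtype=bool)
    true_fc = np.ones(cfg.n_peaks)
    if cfg.n_de:
        de_idx = rng.choice(cfg.n_peaks, size=cfg.n_de, replace=False)
        is_de[de_idx] = True
        true_fc[np.sort(de_idx)] = cfg.fold_change_vector()
    cancer_means = normal_means * true_fc

    baseline = cfg.baseline_amplitude * np.exp(-grid / cfg.baseline_decay)

    spectra: list[Spectrum] = []
    groups = [("cancer", cfg.n_cancer, cancer_means), ("normal", cfg.n_normal, normal_means)]
    for group, n_samples, means in groups:
        for s in range(n_samples):
            sample_id = f"{group[0].upper()}{s + 1:03d}"
            # per-sample biological factor, shared by replicates; E = means
            bio = np.exp(
                rng.normal(-cfg.biological_cv**2 / 2, cfg.biological_cv, cfg.n_peaks)
            )
            heights = means * bio
            for r in range(cfg.n_replicates):
                jitter = rng.normal(0.0, cfg.mz_jitter_sd) if cfg.mz_jitter_sd else 0.0
                scale = (
                    np.exp(rng.normal(-cfg.scale_sd**2 / 2, cfg.scale_sd))
                    if cfg.scale_sd
                    else 1.0
                )
                signal = baseline.copy()
                for c, sig, h in zip(centers + jitter, sigmas, heights):
                    lo_i = np.searchsorted(grid, c - 6 * sig)
                    hi_i = np.searchsorted(grid, c + 6 * sig)
                    window = grid[lo_i:hi_i]
                    signal[lo_i:hi_i] += h * np.exp(-((window - c) ** 2) / (2 * sig**2))
                y = scale * signal
                if cfg.noise_sd:
                    y = y + rng.normal(0.0, cfg.noise_sd, size=grid.size)
                spectra.append(
                    Spectrum(grid, y, sample_id=sample_id, replicate_id=r, group=group)
                )

    truth = GroundTruth(
        true_mz=centers,
        is_de=is_de,
        true_fc=true_fc,
        group_means=pd.DataFrame({"cancer": cancer_means, "normal": normal_means}),
    )
    return SpectrumSet(spectra), truth


def simulate_pvalue_mixture(
    n_tests: int,
    pi0: float,
    effect: float,
    strata_assignment: np.ndarray | None = None,
    alt_stratum=None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-null / normal-shift-alternative p-value mixture.

    Nulls are U(0,1); each alternative is the one-sided p-value of a
    N(effect, 1) draw against N(0, 1). With ``strata_assignment`` given,
    alternative positions are drawn inside ``alt_stratum`` (default: the
    smallest stratum), concentrating the signal the way high-fold-change
    strata concentrate true DE peaks.

    Returns (p_values, is_alternative).
    """
    if not 0 <= pi0 <= 1:
        raise ConfigError("pi0 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_alt = int(round((1 - pi0) * n_tests))
    p = rng.uniform(size=n_tests)
    is_alt = np.zeros(n_tests, dtype=bool)
    if n_alt:
        if strata_assignment is not None:
            strata_assignment = np.asarray(strata_assignment)
            if strata_assignment.size != n_tests:
                raise ConfigError("strata_assignment must have one label per test")
            if alt_stratum is None:
                labels, counts = np.unique(strata_assignment, return_counts=True)
                alt_stratum = labels[np.argmin(counts)]
            pool = np.flatnonzero(strata_assignment == alt_stratum)
            if pool.size < n_alt:
                raise ConfigError(
                    f"stratum {alt_stratum!r} holds {pool.size} tests, "
                    f"fewer than {n_alt} alternatives"
                )
            positions = rng.choice(pool, size=n_alt, replace=False)
        else:
            positions = rng.choice(n_tests, size=n_alt, replace=False)
        is_alt[positions] = True
        p[positions] = stats.norm.sf(rng.normal(effect, 1.0, size=n_alt))
    return p, is_alt


def evaluate_detection(
    detected_mz: np.ndarray, truth: GroundTruth, shift: float = 0.003
) -> tuple[float, float]:
    """Sensitivity and empirical FDR of a detected peak list.

    Detected peaks are matched one-to-one to true peaks within a relative
    window of ±shift·m/z. Sensitivity = matched true peaks / all true
    peaks; FDR = unmatched detected peaks / all detected peaks; an empty
    denominator yields 0.
    """
    if shift <= 0:
        raise ConfigError("shift must be positive")
    detected = np.sort(np.asarray(detected_mz, dtype=float))
    result = match_peaks(truth.true_mz, detected, shift)
    n_true = truth.true_mz.size
    n_det = detected.size
    sensitivity = result.k / n_true if n_true else 0.0
    fdr = (n_det - result.k) / n_det if n_det else 0.0
    return sensitivity, fdr
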