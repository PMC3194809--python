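"""Experiment harness: the three reproducibility analyses.

* SNR sweep — peak-level and DE-level consistency between one
  procedure at a range of SNR thresholds and a reference procedure at
  its default threshold.
* Subsampling power — mean DE count and mean DE-level PO over repeated
  group-proportion-preserving subsamples at several sample sizes.
* Stratified-vs-simple comparison — the same DE table selected under
  profile-wide BH and under fold-change-stratified BH, scored against
  the simulation ground truth.

Every run is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .consistency import consistency_report, po_score
from .differential import (
    DEFAULT_Q,
    StratifiedConfig,
    select_de,
    test_peaks,
)
from .errors import ConfigError, DataError
from .matching import DEFAULT_SHIFT, consensus_by_sample, match_peaks, restrict_mz_range
from .preprocess import PRESET_DEFAULT_SNR, run_preset
from .profiles import PeakProfile
from .simulate import GroundTruth, SimulationConfig, simulate_dataset
from .spectra import SpectrumSet

__all__ = [
    "ExperimentConfig",
    "preset_consensus_profile",
    "run_snr_sweep",
    "run_subsample_power",
    "run_stratified_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # grids span each preset's informative range on the default
    # simulation: the high end prunes true peaks (small profiles), the
    # low end keeps them all
    snr_grids: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "specalign_like": (1.5, 20.0, 40.0, 80.0),
            "cromwell_like": (2.0, 5.0, 300.0),
        }
    )
    default_snrs: dict[str, float] = field(
        default_factory=lambda: dict(PRESET_DEFAULT_SNR)
    )
    mz_window: tuple[float, float] | None = None
    shift: float = DEFAULT_SHIFT
    q_level: float = DEFAULT_Q
    stratified: bool = False
    subsample_sizes: tuple[int, ...] = (12, 21, 30, 45)
    n_subsample_reps: int = 100
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsample_reps < 1:
            raise ConfigError("n_subsample_reps must be >= 1")
        if not 0 < self.q_level < 1:
            raise ConfigError("q_level must lie in (0, 1)")


def preset_consensus_profile(
    spectra: SpectrumSet,
    preset: str,
    snr_threshold: float | None = None,
    mz_window: tuple[float, float] | None = None,
    **params,
) -> PeakProfile:
    """Pre-process all spectra with one preset, collapse technical
    replicates to per-sample consensus rows, and optionally restrict the
    analysis m/z window."""
    profile = run_preset(spectra, preset, snr_threshold, **params)
    profile = consensus_by_sample(profile)
    if mz_window is not None:
        profile = restrict_mz_range(profile, *mz_window)
    return profile


def _de_list(table: pd.DataFrame):
    de = table[table["significant"]]
    return de["mz"].to_numpy(), de["direction"].to_numpy()


def _profile_de(profile: PeakProfile, q_level, stratified, seed):
    table = test_peaks(profile)
    cfg = StratifiedConfig(q_level=q_level, seed=seed)
    return select_de(table, q_level, stratified=stratified, config=cfg)


def run_snr_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Sweep SNR thresholds per preset against reference presets at
    their defaults; report counts and peak/DE-level consistency.

    One row per (preset, snr, reference): number of detected peaks and
    DE peaks for the swept run, plus PO/nPO/p at peak level and — when
    both DE lists are non-empty — at DE level.
    """
    if len(config.snr_grids) < 1:
        raise ConfigError("snr_grids must name at least one preset")
    spectra, _truth = simulate_dataset(config.simulation)

    references: dict[str, tuple[PeakProfile, pd.DataFrame]] = {}
    for preset in config.snr_grids:
        ref_snr = config.default_snrs.get(preset, PRESET_DEFAULT_SNR[preset])
        prof = preset_consensus_profile(
            spectra, preset, ref_snr, config.mz_window
        )
        references[preset] = (
            prof,
            _profile_de(prof, config.q_level, config.stratified, config.seed),
        )

    universe = spectra.mz
    if config.mz_window is not None:
        low, high = config.mz_window
        universe = universe[(universe >= low) & (universe <= high)]

    rows = []
    for preset, grid in config.snr_grids.items():
        for snr in grid:
            prof = preset_consensus_profile(
                spectra, preset, snr, config.mz_window
            )
            table = _profile_de(prof, config.q_level, config.stratified, config.seed)
            de_mz, de_dir = _de_list(table)
            for ref_name, (ref_prof, ref_table) in references.items():
                row = {
                    "preset": preset,
                    "snr": snr,
                    "reference": ref_name,
                    "n_peaks": prof.n_peaks,
                    "n_de": int(de_mz.size),
                    "ref_n_peaks": ref_prof.n_peaks,
                }
                if prof.n_peaks and ref_prof.n_peaks:
                    rep = consistency_report(
                        prof.peak_mz,
                        ref_prof.peak_mz,
                        universe,
                        universe,
                        shift=config.shift,
                        n_perm=config.n_perm,
                        seed=config.seed,
                    )
                    row.update(po=rep.po, n_po=rep.n_po, p=rep.p_value, k=rep.k)
                ref_de_mz, ref_de_dir = _de_list(ref_table)
                row["ref_n_de"] = int(ref_de_mz.size)
                if de_mz.size and ref_de_mz.size:
                    rep = consistency_report(
                        de_mz,
                        ref_de_mz,
                        prof.peak_mz,
                        ref_prof.peak_mz,
                        shift=config.shift,
                        n_perm=config.n_perm,
                        seed=config.seed,
                        directions_1=de_dir,
                        directions_2=ref_de_dir,
                        universe_directions_1=table["direction"].to_numpy(),
                        universe_directions_2=ref_table["direction"].to_numpy(),
                    )
                    row.update(
                        po_de=rep.po, n_po_de=rep.n_po, p_de=rep.p_value, k_de=rep.k
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def _stratified_subsample_rows(
    groups: np.ndarray, size: int, full_counts: dict[str, int], rng
) -> np.ndarray | None:
    """Indices of a subsample of ``size`` rows preserving group proportions."""
    n_total = groups.size
    idx = []
    for label, n_g in full_counts.items():
        take = int(round(size * n_g / n_total))
        take = min(max(take, 0), n_g)
        pool = np.flatnonzero(groups == label)
        if take < 2:
            return None
        idx.append(rng.choice(pool, size=take, replace=False))
    return np.sort(np.concatenate(idx))


def run_subsample_power(
    config: ExperimentConfig,
    profiles: dict[str, PeakProfile] | None = None,
) -> dict[str, pd.DataFrame]:
    """Mean DE counts and pairwise DE consistency over random subsamples.

    For each sample size, ``n_subsample_reps`` subsets are drawn with
    the cancer/normal proportions of the full cohort held fixed; DE
    peaks are selected per preset profile at ``q_level`` and the
    direction-aware PO between every preset pair recorded (a subset
    where either profile finds no DE peak scores 0 — zero reproduced
    discoveries; ``n_scored`` counts the subsets where both lists were
    non-empty). Returns
    ``{"de_counts": ..., "consistency": ...}`` tables of per-size means.
    Sizes leaving fewer than 2 samples in a group are skipped.
    """
    if profiles is None:
        spectra, _ = simulate_dataset(config.simulation)
        profiles = {
            preset: preset_consensus_profile(
                spectra,
                preset,
                config.default_snrs.get(preset, PRESET_DEFAULT_SNR[preset]),
                config.mz_window,
            )
            for preset in config.snr_grids
        }
    presets = list(profiles)
    first = profiles[presets[0]]
    groups = np.asarray(first.groups)
    for p in profiles.values():
        if p.groups != first.groups:
            raise DataError("profiles must cover the same samples")
    full_counts = {g: int((groups == g).sum()) for g in np.unique(groups)}
    rng = np.random.default_rng(config.seed)

    count_rows, cons_rows = [], []
    for size in config.subsample_sizes:
        if size > groups.size:
            raise ConfigError(f"subsample size {size} exceeds cohort {groups.size}")
        n_de_acc = {p: [] for p in presets}
        po_acc = {pair: [] for pair in _pairs(presets)}
        scored = {pair: 0 for pair in _pairs(presets)}
        skipped = False
        for _ in range(config.n_subsample_reps):
            idx = _stratified_subsample_rows(groups, size, full_counts, rng)
            if idx is None:
                logger.warning("size %d leaves < 2 samples in a group; skipped", size)
                skipped = True
                break
            tables = {}
            for preset in presets:
                prof = profiles[preset]
                sub = replace(
                    prof,
                    intensity_matrix=prof.intensity_matrix[idx],
                    sample_ids=[prof.sample_ids[i] for i in idx],
                    replicate_ids=[prof.replicate_ids[i] for i in idx],
                    groups=[prof.groups[i] for i in idx],
                )
                tables[preset] = _profile_de(
                    sub, config.q_level, config.stratified, config.seed
                )
                n_de_acc[preset].append(int(tables[preset]["significant"].sum()))
            for a, b in po_acc:
                mza, dira = _de_list(tables[a])
                mzb, dirb = _de_list(tables[b])
                if mza.size and mzb.size:
                    _, po = po_score(mza, mzb, config.shift, dira, dirb)
                    scored[(a, b)] += 1
                else:
                    # a subset where either profile finds no DE peak
                    # contributes zero reproducibility
                    po = 0.0
                po_acc[(a, b)].append(po)
        if skipped:
            continue
        for preset in presets:
            count_rows.append(
                {
                    "size": size,
                    "preset": preset,
                    "mean_n_de": float(np.mean(n_de_acc[preset])),
                }
            )
        for (a, b), vals in po_acc.items():
            cons_rows.append(
                {
                    "size": size,
                    "pair": f"{a}|{b}",
                    "mean_po_de": float(np.mean(vals)) if vals else np.nan,
                    "n_scored": scored[(a, b)],
                }
            )
    return {
        "de_counts": pd.DataFrame(count_rows),
        "consistency": pd.DataFrame(cons_rows),
    }


def _pairs(names):
    return [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]


def run_stratified_comparison(
    config: ExperimentConfig,
    profile: PeakProfile | None = None,
    truth: GroundTruth | None = None,
    preset: str = "cromwell_like",
) -> pd.DataFrame:
    """Simple vs stratified BH selection on one profile, scored against
    ground truth.

    Returns one row per mode with the discovery count, and — via
    matching the profile's peaks to the true peak list — the empirical
    FDR and power of the selected set with respect to the truly DE
    peaks.
    """
    if profile is None or truth is None:
        spectra, truth = simulate_dataset(config.simulation)
        profile = preset_consensus_profile(
            spectra,
            preset,
            config.default_snrs.get(preset, PRESET_DEFAULT_SNR[preset]),
            config.mz_window,
        )
    table = test_peaks(profile)

    # map profile peaks onto true peaks to know which are truly DE
    m = match_peaks(profile.peak_mz, truth.true_mz, config.shift)
    truly_de = np.zeros(profile.n_peaks, dtype=bool)
    for i, j in m.pairs:
        truly_de[i] = truth.is_de[j]

    rows = []
    for mode, stratified in (("simple", False), ("stratified", True)):
        sel = select_de(
            table,
            config.q_level,
            stratified=stratified,
            config=StratifiedConfig(q_level=config.q_level, seed=config.seed),
        )
        flags = sel["significant"].to_numpy()
        n_sel = int(flags.sum())
        tp = int((flags & truly_de).sum())
        rows.append(
            {
                "mode": mode,
                "n_de": n_sel,
                "n_true_de_found": tp,
                "empirical_fdr": (n_sel - tp) / n_sel if n_sel else 0.0,
                "power": tp / truly_de.sum() if truly_de.any() else np.nan,
                "n_strata": int(sel["stratum"].nunique()),
            }
        )
    return pd.DataFrame(rows)
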