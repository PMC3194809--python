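"""Differential peak testing with simple and stratified FDR control.

Per peak, an equal-variance two-sample Student's t-test compares cancer
against normal intensities and the fold change (FC) is the cancer/normal
mean ratio. Discoveries are selected with the Benjamini-Hochberg (BH)
step-up procedure, either on all peaks at once (simple) or within fold-
change strata (stratified): peaks are partitioned by 1-D k-means on
|log2 FC|, the number of strata picked by maximal mean silhouette, and
BH run independently in each stratum at the same level. Because the
per-stratum discovery sets are disjoint, the FDR of their union stays
below the nominal level, while small high-FC strata escape the heavy
multiplicity burden of a large profile — the mechanism that lets a
large peak profile recover discoveries a profile-wide BH pass misses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .profiles import PeakProfile

__all__ = [
    "StratifiedConfig",
    "test_peaks",
    "bh_select",
    "stratify_by_fc",
    "stratified_select",
    "select_de",
]

logger = logging.getLogger(__name__)

DEFAULT_Q = 0.10  # conventional FDR level for DE peak selection


@dataclass
class StratifiedConfig:
    """Parameters of the fold-change stratification."""

    q_level: float = DEFAULT_Q
    k_range: tuple[int, ...] = tuple(range(2, 11))
    n_restarts: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q_level < 1:
            raise ConfigError("q_level must lie in (0, 1)")
        if min(self.k_range) < 2:
            raise ConfigError("k_range values must be >= 2")


def test_peaks(
    profile: PeakProfile,
    labels: list[str] | None = None,
    cancer_label: str = "cancer",
    normal_label: str = "normal",
    log2: bool = False,
) -> pd.DataFrame:
    """Per-peak Student's t-test (equal variances) of cancer vs normal.

    Returns a DE table with columns ``mz, t_stat, p_value, fc,
    direction, stratum, significant, q_level``; ``fc`` is the raw-scale
    cancer/normal mean ratio regardless of ``log2``, which only switches
    the scale the t-test runs on (with a +1 offset to keep zeros finite).
    """
    groups = np.asarray(labels if labels is not None else profile.groups)
    cancer = profile.intensity_matrix[groups == cancer_label]
    normal = profile.intensity_matrix[groups == normal_label]
    if cancer.shape[0] < 2 or normal.shape[0] < 2:
        raise DataError(
            f"need >= 2 samples per group, got {cancer.shape[0]} "
            f"{cancer_label} / {normal.shape[0]} {normal_label}"
        )
    xc, xn = (np.log2(cancer + 1), np.log2(normal + 1)) if log2 else (cancer, normal)
    t_stat, p_value = stats.ttest_ind(xc, xn, axis=0, equal_var=True)

    mean_c = cancer.mean(axis=0)
    mean_n = normal.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_n > 0, mean_c / mean_n, np.inf)
    fc = np.where((mean_n == 0) & (mean_c == 0), 1.0, fc)

    # degenerate peaks: zero pooled variance gives nan t / p
    degenerate = ~np.isfinite(p_value)
    if degenerate.any():
        same = np.isclose(mean_c, mean_n)
        with np.errstate(invalid="ignore"):
            p_value = np.where(degenerate, np.where(same, 1.0, np.nextafter(0, 1)), p_value)
            t_stat = np.where(
                degenerate, np.where(same, 0.0, np.inf * np.sign(mean_c - mean_n)), t_stat
            )
        logger.warning("%d peaks had zero pooled variance", int(degenerate.sum()))

    direction = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
    return pd.DataFrame(
        {
            "mz": profile.peak_mz,
            "t_stat": t_stat,
            "p_value": p_value,
            "fc": fc,
            "direction": direction,
            "stratum": 0,
            "significant": False,
            "q_level": np.nan,
        }
    )


def bh_select(p_values: np.ndarray, q_level: float) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up selection at level ``q_level``.

    Returns (significance flags, realized p-value cutoff); the cutoff is
    the largest order statistic p_(i) with p_(i) <= i*q/m, or 0 when
    nothing is selected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    flags = multipletests(p, alpha=q_level, method="fdr_bh")[0]
    cutoff = float(p[flags].max()) if flags.any() else 0.0
    return flags, cutoff


def stratify_by_fc(
    table: pd.DataFrame, config: StratifiedConfig | None = None
) -> tuple[np.ndarray, int]:
    """Partition peaks into fold-change strata by 1-D k-means.

    The stratification value is |log2 FC| (so strong up- and
    down-regulation land together in the high stratum; infinite FC is
    mapped above the largest finite value). Each k in ``k_range`` is fit
    with ``n_restarts`` seeded restarts; the k with the highest mean
    silhouette wins, ties going to the smaller k. Strata are labelled
    0, 1, ... in order of increasing centre. Returns (assignment,
    chosen k); degenerate FC vectors fall back to a single stratum.
    """
    cfg = config or StratifiedConfig()
    fc = table["fc"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        values = np.abs(np.log2(fc))
    finite = np.isfinite(values)
    if finite.any() and not finite.all():
        values[~finite] = values[finite].max() * 2 + 10.0
    elif not finite.any():
        values[:] = 0.0

    n = values.size
    ks = [k for k in cfg.k_range if k < n]
    if np.unique(values).size < 2 or not ks:
        logger.warning("fold changes carry no structure; using a single stratum")
        return np.zeros(n, dtype=int), 1
    if n < max(cfg.k_range) + 1:
        logger.warning(
            "only %d peaks for k_range up to %d; larger k skipped", n, max(cfg.k_range)
        )

    x = values.reshape(-1, 1)
    best_k, best_sil, best_labels = None, -np.inf, None
    for k in ks:
        if np.unique(values).size < k:
            continue
        km = KMeans(n_clusters=k, n_init=cfg.n_restarts, random_state=cfg.seed)
        labels = km.fit_predict(x)
        sil = silhouette_score(x, labels)
        if sil > best_sil + 1e-12:  # strict: ties keep the smaller k
            best_k, best_sil, best_labels = k, sil, labels
    if best_k is None:
        return np.zeros(n, dtype=int), 1

    # relabel strata by increasing centre so 0 = lowest |log2 FC|
    centers = np.array(
        [values[best_labels == lab].mean() for lab in range(best_k)]
    )
    order = np.argsort(centers)
    remap = np.empty(best_k, dtype=int)
    remap[order] = np.arange(best_k)
    return remap[best_labels], best_k


def stratified_select(
    table: pd.DataFrame, assignment: np.ndarray, q_level: float = DEFAULT_Q
) -> pd.DataFrame:
    """BH selection run independently inside each stratum at ``q_level``.

    The union of per-stratum discoveries is reported; disjointness keeps
    the overall FDR at or below the nominal level.
    """
    assignment = np.asarray(assignment)
    if assignment.size != len(table):
        raise DataError("stratum assignment must cover every peak")
    out = table.copy()
    out["stratum"] = assignment
    out["significant"] = False
    out["q_level"] = q_level
    for stratum in np.unique(assignment):
        idx = np.flatnonzero(assignment == stratum)
        flags, _ = bh_select(out["p_value"].to_numpy()[idx], q_level)
        out.iloc[idx, out.columns.get_loc("significant")] = flags
    return out


def select_de(
    table: pd.DataFrame,
    q_level: float = DEFAULT_Q,
    stratified: bool = False,
    config: StratifiedConfig | None = None,
) -> pd.DataFrame:
    """Convenience: simple or stratified BH selection on a DE table."""
    if stratified:
        cfg = config or StratifiedConfig(q_level=q_level)
        assignment, _ = stratify_by_fc(table, cfg)
        return stratified_select(table, assignment, q_level)
    out = table.copy()
    flags, _ = bh_select(out["p_value"].to_numpy(), q_level)
    out["stratum"] = 0
    out["significant"] = flags
    out["q_level"] = q_level
    return out
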