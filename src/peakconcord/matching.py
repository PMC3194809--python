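"""Cross-profile peak bookkeeping.

Two peaks from different pre-processing runs are treated as the same
molecular species when their m/z values differ by less than a relative
shift window (±0.1–0.3% is conventional for SELDI data; ±0.3% is the
default here). Matching is greedy one-to-one in order of increasing
relative distance, which is deterministic and, at these window sizes,
coincides with optimal assignment on realistic peak lists.

Also hosts the duplicate-spectrum consensus step (the two technical
replicates of each sample are pre-processed separately and their
quantified rows averaged) and the m/z-range restriction applied before
any downstream analysis (e.g. 1–10 kDa or 2–40 kDa).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError
from .profiles import PeakProfile

__all__ = [
    "MatchResult",
    "match_peaks",
    "consensus_profile",
    "consensus_by_sample",
    "restrict_mz_range",
]

logger = logging.getLogger(__name__)

DEFAULT_SHIFT = 0.003


@dataclass
class MatchResult:
    """One-to-one matching of two sorted peak lists.

    ``pairs`` holds (index in A, index in B); the window is anchored on
    list A: a pair is admissible iff |mzA - mzB| <= shift * mzA.
    """

    pairs: list[tuple[int, int]]
    shift: float
    unmatched_a: list[int]
    unmatched_b: list[int]

    @property
    def k(self) -> int:
        return len(self.pairs)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "shift": self.shift,
                "pairs": [list(p) for p in self.pairs],
                "unmatched_a": self.unmatched_a,
                "unmatched_b": self.unmatched_b,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "MatchResult":
        d = json.loads(text)
        return cls(
            pairs=[tuple(p) for p in d["pairs"]],
            shift=d["shift"],
            unmatched_a=d["unmatched_a"],
            unmatched_b=d["unmatched_b"],
        )


def match_peaks(
    list_a: np.ndarray, list_b: np.ndarray, shift: float = DEFAULT_SHIFT
) -> MatchResult:
    """Greedily match two sorted m/z lists within a relative shift window.

    Candidate pairs (all within the window) are visited in order of
    increasing relative distance |mzA - mzB| / mzA, ties broken by index,
    and accepted when both endpoints are still free — a deterministic
    one-to-one matching.
    """
    if shift < 0:
        raise ConfigError(f"shift must be non-negative, got {shift}")
    a = np.asarray(list_a, dtype=float)
    b = np.asarray(list_b, dtype=float)
    if np.any(np.diff(a) < 0) or np.any(np.diff(b) < 0):
        raise DataError("peak lists must be sorted by m/z")

    candidates: list[tuple[float, int, int]] = []
    for i, mza in enumerate(a):
        tol = shift * mza
        lo = np.searchsorted(b, mza - tol, side="left")
        hi = np.searchsorted(b, mza + tol, side="right")
        for j in range(lo, hi):
            candidates.append((abs(mza - b[j]) / mza if mza else np.inf, i, j))
    candidates.sort()

    used_a = np.zeros(a.size, dtype=bool)
    used_b = np.zeros(b.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            pairs.append((i, j))
    pairs.sort()
    return MatchResult(
        pairs=pairs,
        shift=shift,
        unmatched_a=[int(i) for i in np.flatnonzero(~used_a)],
        unmatched_b=[int(j) for j in np.flatnonzero(~used_b)],
    )


def consensus_profile(rep1: PeakProfile, rep2: PeakProfile) -> PeakProfile:
    """Average the quantified matrices of two technical-replicate profiles.

    Both profiles must come from the same detection run (identical peak
    sets) and cover the same biological samples in the same order; the
    consensus has one row per sample.
    """
    if rep1.n_peaks != rep2.n_peaks or not np.allclose(rep1.peak_mz, rep2.peak_mz):
        raise DataError("replicate profiles carry different peak sets")
    if rep1.sample_ids != rep2.sample_ids:
        raise DataError(
            "replicate profiles cover different samples or sample orders"
        )
    if rep1.groups != rep2.groups:
        raise DataError("replicate profiles disagree on group labels")
    return replace(
        rep1,
        intensity_matrix=(rep1.intensity_matrix + rep2.intensity_matrix) / 2.0,
        replicate_ids=[-1] * rep1.n_rows,  # -1 marks a consensus row
    )


def consensus_by_sample(profile: PeakProfile) -> PeakProfile:
    """Collapse a per-spectrum profile into one consensus row per sample.

    Splits rows by replicate id and reduces them pairwise with
    :func:`consensus_profile` (generalising to any replicate count by
    plain averaging when there are more than two).
    """
    reps = sorted(set(profile.replicate_ids))
    if len(reps) == 1:
        return profile
    order: dict[str, None] = {}
    for s in profile.sample_ids:
        order.setdefault(s)
    samples = list(order)

    row_of = {
        (sid, rid): i
        for i, (sid, rid) in enumerate(
            zip(profile.sample_ids, profile.replicate_ids)
        )
    }

    def rows_for(rep: int) -> PeakProfile:
        try:
            idx = [row_of[(s, rep)] for s in samples]
        except KeyError as exc:
            raise DataError(
                f"sample missing replicate {rep}: {exc.args[0]}"
            ) from None
        return replace(
            profile,
            intensity_matrix=profile.intensity_matrix[idx],
            sample_ids=[profile.sample_ids[i] for i in idx],
            replicate_ids=[profile.replicate_ids[i] for i in idx],
            groups=[profile.groups[i] for i in idx],
        )

    per_rep = [rows_for(r) for r in reps]
    if len(per_rep) == 2:
        return consensus_profile(per_rep[0], per_rep[1])
    mean = np.mean([p.intensity_matrix for p in per_rep], axis=0)
    return replace(
        per_rep[0], intensity_matrix=mean, replicate_ids=[-1] * len(samples)
    )


def restrict_mz_range(profile: PeakProfile, low: float, high: float) -> PeakProfile:
    """Keep peaks with low <= m/z <= high (closed interval)."""
    if not low < high:
        raise ConfigError(f"need low < high, got [{low}, {high}]")
    keep = (profile.peak_mz >= low) & (profile.peak_mz <= high)
    if profile.n_peaks and not keep.any():
        logger.warning(
            "m/z restriction [%g, %g] removed all %d peaks",
            low, high, profile.n_peaks,
        )
    return profile.select_peaks(keep)
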