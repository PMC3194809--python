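"""Percentage-of-overlap (PO) consistency scoring with permutation nulls.

For peak lists of lengths l1 <= l2 sharing k peaks (within a relative
m/z shift window), PO = k / l1: the fraction of the shorter list covered
by the longer one. Because PO depends on the list lengths, it is
normalised against its chance expectation E(PO), estimated as the mean
PO of random list pairs of the same lengths drawn from the two
underlying m/z universes:

    nPO = (PO - E(PO)) / (1 - E(PO)),

the observed excess over chance relative to the maximum possible excess.
The permutation p-value is the plain proportion of null PO values at or
above the observed one (resolution floor 1 / n_perm).

For differentially expressed (DE) peak lists, a peak only counts as
shared when it is regulated in the same direction in both lists, and
null lists are drawn from the profiles' detected-peak universes carrying
each drawn peak's observed direction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError
from .matching import DEFAULT_SHIFT, match_peaks

__all__ = ["ConsistencyReport", "po_score", "null_distribution", "consistency_report"]

logger = logging.getLogger(__name__)


@dataclass
class ConsistencyReport:
    l1: int                 # shorter list length
    l2: int                 # longer list length
    k: int                  # shared peaks (direction-aware when applicable)
    po: float               # k / l1
    e_po: float             # permutation mean of null PO
    n_po: float             # (po - e_po) / (1 - e_po)
    p_value: float
    n_perm: int
    direction_aware: bool
    shift: float
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self))
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "ConsistencyReport":
        return cls(**json.loads(text))


def _sorted_with_directions(mz, directions):
    mz = np.asarray(mz, dtype=float)
    if directions is None:
        order = np.argsort(mz, kind="stable")
        return mz[order], None
    directions = np.asarray(directions)
    if directions.size != mz.size:
        raise DataError("one direction per peak required")
    order = np.argsort(mz, kind="stable")
    return mz[order], directions[order]


def _shared_count(mz1, dir1, mz2, dir2, shift) -> int:
    """k between two sorted lists; with directions, matching runs within
    each direction separately and 'none' peaks can never be shared."""
    if dir1 is None:
        return match_peaks(mz1, mz2, shift).k
    k = 0
    for d in ("up", "down"):
        k += match_peaks(mz1[dir1 == d], mz2[dir2 == d], shift).k
    return k


def po_score(
    list_1,
    list_2,
    shift: float = DEFAULT_SHIFT,
    directions_1=None,
    directions_2=None,
) -> tuple[int, float]:
    """Shared-peak count and PO score from the shorter list to the longer.

    The roles are assigned so list 1 is the shorter; with directions
    supplied a shared peak must agree in direction.
    """
    if shift <= 0:
        raise ConfigError("shift must be positive")
    mz1, d1 = _sorted_with_directions(list_1, directions_1)
    mz2, d2 = _sorted_with_directions(list_2, directions_2)
    if (d1 is None) != (d2 is None):
        raise DataError("directions must be given for both lists or neither")
    if mz2.size < mz1.size:
        mz1, mz2, d1, d2 = mz2, mz1, d2, d1
    if mz1.size == 0:
        raise DataError("PO is undefined for an empty shorter list")
    k = _shared_count(mz1, d1, mz2, d2, shift)
    return k, k / mz1.size


def null_distribution(
    universe_1,
    universe_2,
    l1: int,
    l2: int,
    shift: float = DEFAULT_SHIFT,
    n_perm: int = 1000,
    seed: int = 0,
    directions_1=None,
    directions_2=None,
) -> tuple[float, np.ndarray]:
    """Null PO distribution for random list pairs of lengths (l1, l2).

    Each permutation samples l1 peaks without replacement from universe
    1 and l2 from universe 2 and scores their overlap; drawn peaks carry
    their universe's observed direction when directions are supplied.
    Returns (E(PO), the n_perm null PO values).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    u1, du1 = _sorted_with_directions(universe_1, directions_1)
    u2, du2 = _sorted_with_directions(universe_2, directions_2)
    if l1 > u1.size or l2 > u2.size:
        raise DataError("list lengths exceed their universes")
    if l1 < 1 or l2 < 1:
        raise ConfigError("list lengths must be >= 1")
    rng = np.random.default_rng(seed)
    denom = min(l1, l2)
    samples = np.empty(n_perm)
    for i in range(n_perm):
        i1 = np.sort(rng.choice(u1.size, size=l1, replace=False))
        i2 = np.sort(rng.choice(u2.size, size=l2, replace=False))
        a, da = u1[i1], None if du1 is None else du1[i1]
        b, db = u2[i2], None if du2 is None else du2[i2]
        if l2 < l1:
            a, b, da, db = b, a, db, da
        samples[i] = _shared_count(a, da, b, db, shift) / denom
    return float(samples.mean()), samples


def consistency_report(
    list_1,
    list_2,
    universe_1,
    universe_2,
    shift: float = DEFAULT_SHIFT,
    n_perm: int = 1000,
    seed: int = 0,
    directions_1=None,
    directions_2=None,
    universe_directions_1=None,
    universe_directions_2=None,
) -> ConsistencyReport:
    """Full consistency report between two peak lists.

    Null lists are drawn from the universes with lengths matching the
    observed lists (roles fixed so list 1 is the shorter). In
    direction-aware mode the observed lists carry their DE directions
    and null draws inherit the directions observed in their source
    universe (the profile's DE table).
    """
    mz1 = np.asarray(list_1, dtype=float)
    mz2 = np.asarray(list_2, dtype=float)
    direction_aware = directions_1 is not None
    if mz2.size < mz1.size:  # fix roles: universe follows its list
        mz1, mz2 = mz2, mz1
        universe_1, universe_2 = universe_2, universe_1
        directions_1, directions_2 = directions_2, directions_1
        universe_directions_1, universe_directions_2 = (
            universe_directions_2,
            universe_directions_1,
        )
    k, po = po_score(mz1, mz2, shift, directions_1, directions_2)
    e_po, samples = null_distribution(
        universe_1,
        universe_2,
        mz1.size,
        mz2.size,
        shift=shift,
        n_perm=n_perm,
        seed=seed,
        directions_1=universe_directions_1,
        directions_2=universe_directions_2,
    )
    if e_po >= 1.0:
        logger.warning("degenerate universes: E(PO) = 1; reporting nPO = 1")
        n_po = 1.0
    else:
        n_po = (po - e_po) / (1.0 - e_po)
    p_value = float(np.mean(samples >= po))
    return ConsistencyReport(
        l1=int(mz1.size),
        l2=int(mz2.size),
        k=int(k),
        po=float(po),
        e_po=float(e_po),
        n_po=float(n_po),
        p_value=p_value,
        n_perm=int(n_perm),
        direction_aware=bool(direction_aware),
        shift=float(shift),
        seed=int(seed),
    )
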