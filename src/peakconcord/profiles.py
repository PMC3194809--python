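"""Peak profile: the output of a pre-processing run.

A profile couples the peak positions detected on the average spectrum
with a samples × peaks matrix of quantified intensities, the half-open
grid intervals that delimit each peak, and provenance (preset name, SNR
threshold). Serialized as a CSV (first column ``sample_id``, remaining
columns the peak m/z values) plus a JSON sidecar carrying everything the
CSV cannot (intervals, grid, replicate ids, groups, provenance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["PeakProfile"]


@dataclass
class PeakProfile:
    peak_mz: np.ndarray                      # (n_peaks,) strictly increasing, Da
    intervals: list[tuple[int, int]]         # half-open index ranges on mz_grid
    intensity_matrix: np.ndarray             # (n_rows, n_peaks), >= 0
    sample_ids: list[str]
    replicate_ids: list[int]
    groups: list[str]
    preset: str = ""
    snr_threshold: float = float("nan")
    mz_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.peak_mz = np.asarray(self.peak_mz, dtype=float)
        self.intensity_matrix = np.atleast_2d(
            np.asarray(self.intensity_matrix, dtype=float)
        )
        self.intervals = [(int(a), int(b)) for a, b in self.intervals]
        if self.peak_mz.size and not np.all(np.diff(self.peak_mz) > 0):
            raise DataError("peak_mz must be strictly increasing")
        if len(self.intervals) != self.peak_mz.size:
            raise DataError("one interval per peak required")
        if self.intensity_matrix.shape[1] != self.peak_mz.size:
            if not (self.peak_mz.size == 0 and self.intensity_matrix.size == 0):
                raise DataError("intensity_matrix must have one column per peak")
        n = self.intensity_matrix.shape[0] if self.intensity_matrix.size else len(self.sample_ids)
        if not (len(self.sample_ids) == len(self.replicate_ids) == len(self.groups)):
            raise DataError("sample_ids/replicate_ids/groups lengths differ")
        if self.intensity_matrix.size and len(self.sample_ids) != n:
            raise DataError("one sample_id per matrix row required")
        for i in range(len(self.intervals) - 1):
            if self.intervals[i][1] > self.intervals[i + 1][0]:
                raise DataError("peak intervals must not overlap")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_mz.size)

    @property
    def n_rows(self) -> int:
        return len(self.sample_ids)

    def select_peaks(self, keep: np.ndarray) -> "PeakProfile":
        """Profile restricted to a boolean/index mask over peaks."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            peak_mz=self.peak_mz[keep],
            intervals=[self.intervals[i] for i in keep],
            intensity_matrix=self.intensity_matrix[:, keep]
            if self.intensity_matrix.size
            else self.intensity_matrix.reshape(self.n_rows, 0),
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> Path:
        """Write ``<path>`` (CSV) and ``<path minus suffix>.json`` sidecar."""
        path = Path(path)
        frame = pd.DataFrame(
            self.intensity_matrix,
            columns=[f"{v:.6f}" for v in self.peak_mz],
        )
        frame.insert(0, "sample_id", self.sample_ids)
        frame.to_csv(path, index=False)
        sidecar = {
            "preset": self.preset,
            "snr_threshold": None if np.isnan(self.snr_threshold) else self.snr_threshold,
            "peak_mz": self.peak_mz.tolist(),
            "intervals": [list(iv) for iv in self.intervals],
            "replicate_ids": list(map(int, self.replicate_ids)),
            "groups": list(self.groups),
            "mz_grid": None if self.mz_grid is None else self.mz_grid.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakProfile":
        path = Path(path)
        frame = pd.read_csv(path, float_precision="round_trip")
        meta = json.loads(path.with_suffix(".json").read_text())
        snr = meta.get("snr_threshold")
        return cls(
            peak_mz=np.asarray(meta["peak_mz"], dtype=float),
            intervals=[tuple(iv) for iv in meta["intervals"]],
            intensity_matrix=frame.drop(columns="sample_id").to_numpy(dtype=float),
            sample_ids=[str(s) for s in frame["sample_id"]],
            replicate_ids=meta["replicate_ids"],
            groups=meta["groups"],
            preset=meta.get("preset", ""),
            snr_threshold=float("nan") if snr is None else float(snr),
            mz_grid=None if meta.get("mz_grid") is None
            else np.asarray(meta["mz_grid"], dtype=float),
        )
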