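"""Mass spectrum container and plain-text I/O.

A :class:`Spectrum` is one SELDI-TOF trace: an increasing m/z axis (Da)
with one intensity per grid point, tagged with the biological sample it
came from, the technical replicate number, and the group label
(``"cancer"`` / ``"normal"``). Spectra are written as two-column CSV
files (``mz,intensity``) next to a tab-separated manifest with columns
``file, sample_id, replicate, group`` — the exchange format every other
module reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["Spectrum", "SpectrumSet", "write_spectra", "read_spectra"]


@dataclass
class Spectrum:
    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_id: int = 0
    group: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise DataError("mz and intensity must be 1-D arrays")
        if self.mz.size != self.intensity.size:
            raise DataError(
                f"mz and intensity lengths differ "
                f"({self.mz.size} vs {self.intensity.size})"
            )
        if self.mz.size < 2:
            raise DataError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.mz) > 0):
            raise DataError("mz must be strictly increasing")

    def __len__(self) -> int:
        return self.mz.size

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with the intensity array replaced."""
        return replace(self, intensity=np.asarray(intensity, dtype=float))

    @property
    def label(self) -> str:
        return f"{self.sample_id}/r{self.replicate_id}"


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one m/z grid."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra:
            grid = self.spectra[0].mz
            for s in self.spectra[1:]:
                if s.mz.size != grid.size or not np.array_equal(s.mz, grid):
                    raise DataError(
                        f"spectrum {s.label} is not on the common m/z grid"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    @property
    def mz(self) -> np.ndarray:
        return self.spectra[0].mz

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.sample_id)
        return list(seen)

    def by_replicate(self, replicate_id: int) -> "SpectrumSet":
        return SpectrumSet(
            [s for s in self.spectra if s.replicate_id == replicate_id]
        )

    @property
    def replicate_ids(self) -> list[int]:
        return sorted({s.replicate_id for s in self.spectra})


def write_spectra(spectra: SpectrumSet | list[Spectrum], outdir: str | Path) -> Path:
    """Write one CSV per spectrum plus ``manifest.tsv``; return the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        fname = f"{s.sample_id}_r{s.replicate_id}.csv"
        pd.DataFrame({"mz": s.mz, "intensity": s.intensity}).to_csv(
            outdir / fname, index=False
        )
        rows.append(
            {"file": fname, "sample_id": s.sample_id,
             "replicate": s.replicate_id, "group": s.group}
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_spectra(manifest: str | Path) -> SpectrumSet:
    """Read a spectrum set back from a manifest written by :func:`write_spectra`."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest, sep="\t")
    required = {"file", "sample_id", "replicate", "group"}
    if not required.issubset(table.columns):
        raise DataError(f"manifest must have columns {sorted(required)}")
    spectra = []
    for row in table.itertuples(index=False):
        data = pd.read_csv(manifest.parent / row.file, float_precision="round_trip")
        spectra.append(
            Spectrum(
                mz=data["mz"].to_numpy(),
                intensity=data["intensity"].to_numpy(),
                sample_id=str(row.sample_id),
                replicate_id=int(row.replicate),
                group=str(row.group),
            )
        )
    return SpectrumSet(spectra)
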