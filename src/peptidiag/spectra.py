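"""Core spectrum container shared by every stage of the workbench.

A :class:`Spectrum` is one sample's profile-mode MALDI-TOF trace: a strictly
increasing m/z axis (Da) and a non-negative intensity array of the same
length.  The ``stage`` tag records provenance through the preprocessing
chain (``raw`` -> ``normalized`` -> ``smoothed`` -> ``baseline_corrected``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STAGES = ("raw", "normalized", "smoothed", "baseline_corrected")


@dataclass
class Spectrum:
    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be one-dimensional")
        if len(self.mz) != len(self.intensity):
            raise ValueError(
                f"length mismatch: {len(self.mz)} m/z values vs "
                f"{len(self.intensity)} intensities"
            )
        if len(self.mz) == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all intensities."""
        return float(self.intensity.sum())

    def with_intensity(self, intensity: np.ndarray, stage: str | None = None) -> "Spectrum":
        """Copy with a new intensity array (and optionally a new stage tag)."""
        return replace(
            self, intensity=np.asarray(intensity, dtype=float),
            stage=self.stage if stage is None else stage,
        )

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(f"spectrum {self.sample_id!r} contains non-finite intensities")
        if not np.all(np.isfinite(self.mz)):
            raise ValueError(f"spectrum {self.sample_id!r} contains non-finite m/z values")


def default_grid(mz_low: float = 1000.0, mz_high: float = 10000.0, step: float = 0.5) -> np.ndarray:
    """Uniform acquisition grid in Da. Default 0.5 Da over [1000, 10000]."""
    if step <= 0:
        raise ValueError("grid step must be positive")
    if mz_low >= mz_high:
        raise ValueError("mz_low must be below mz_high")
    n = int(round((mz_high - mz_low) / step)) + 1
    return mz_low + step * np.arange(n)
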