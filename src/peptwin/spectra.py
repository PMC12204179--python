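"""In-memory spectrum containers shared by every module."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["PeakList", "SpectrumRecord"]


class PeakList:
    """Paired fragment m/z and intensity arrays, kept sorted by m/z.

    The constructor sorts by m/z and merges exact duplicate m/z values by
    summing their intensities, so ``mz`` is strictly increasing — the
    invariant every similarity function here relies on.
    """

    __slots__ = ("mz", "intensity")

    def __init__(self, mz, intensity):
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if mz.ndim != 1 or intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if mz.shape != intensity.shape:
            raise ValueError(
                f"mz and intensity lengths differ: {mz.size} vs {intensity.size}"
            )
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")
        if mz.size and np.any(mz <= 0):
            raise ValueError("m/z values must be positive")
        order = np.argsort(mz, kind="stable")
        mz = mz[order]
        intensity = intensity[order]
        if mz.size > 1 and np.any(np.diff(mz) == 0):
            uniq, inverse = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, intensity)
            mz, intensity = uniq, summed
        self.mz = mz
        self.intensity = intensity
        self.mz.setflags(write=False)
        self.intensity.setflags(write=False)

    def __len__(self) -> int:
        return int(self.mz.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakList):
            return NotImplemented
        return np.array_equal(self.mz, other.mz) and np.array_equal(
            self.intensity, other.intensity
        )

    def __repr__(self) -> str:
        return f"PeakList(n={len(self)})"

    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def scaled(self, max_intensity: float = 1.0) -> "PeakList":
        """Return a copy rescaled so the base peak equals ``max_intensity``."""
        base = self.base_peak_intensity()
        if base == 0:
            return PeakList(self.mz.copy(), self.intensity.copy())
        return PeakList(self.mz.copy(), self.intensity * (max_intensity / base))


@dataclass
class SpectrumRecord:
    """One library spectrum: identity, precursor coordinates and peaks.

    ``retention_kind`` distinguishes predicted iRT (dimensionless) from
    empirical retention time stored in minutes; grouping refuses to mix the
    two, so the flag travels with the value.
    """

    name: str
    precursor_mz: float
    peaks: PeakList
    sequence: Optional[str] = None
    charge: Optional[int] = None
    retention: Optional[float] = None
    retention_kind: Optional[str] = None  # "irt" | "minutes" | None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")
        if self.retention_kind not in (None, "irt", "minutes"):
            raise ValueError(f"unknown retention kind {self.retention_kind!r}")

    def with_peaks(self, peaks: PeakList) -> "SpectrumRecord":
        return replace(self, peaks=peaks)
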