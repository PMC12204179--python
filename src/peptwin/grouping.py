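"""Candidate-pair generation: precursors whose MS1 m/z and iRT both fall
within user tolerances are the pairs whose spectra get compared."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .chem import PeptideIon

logger = logging.getLogger(__name__)

__all__ = ["Tolerance", "GroupingConfig", "PrecursorEntry", "candidate_pairs"]


@dataclass(frozen=True)
class Tolerance:
    """An m/z tolerance, either absolute (Da) or relative (ppm)."""

    value: float
    unit: str = "ppm"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("tolerance must be non-negative")
        if self.unit not in ("Da", "ppm"):
            raise ValueError(f"tolerance unit must be 'Da' or 'ppm', got {self.unit!r}")

    def window(self, mz: float) -> float:
        """Allowed |Δm/z| at reference ``mz`` (the smaller member of a pair)."""
        return self.value if self.unit == "Da" else self.value * 1e-6 * mz


@dataclass(frozen=True)
class GroupingConfig:
    """Defaults match the standard study setup: 10 ppm MS1, ±5 iRT units."""

    mz_tolerance: Tolerance = Tolerance(10.0, "ppm")
    irt_tolerance: float = 5.0

    def __post_init__(self) -> None:
        if self.irt_tolerance < 0:
            raise ValueError("iRT tolerance must be non-negative")


@dataclass(frozen=True)
class PrecursorEntry:
    """A peptide ion placed on the (m/z, iRT) plane; the unit of grouping.

    ``ion`` is None for entries built from library spectra that carry no
    parseable sequence/charge.
    """

    identifier: str
    mz: float
    irt: Optional[float]
    ion: Optional[PeptideIon] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.identifier}: precursor m/z must be positive")


def candidate_pairs(
    entries: Sequence[PrecursorEntry],
    config: GroupingConfig = GroupingConfig(),
) -> list[tuple[int, int]]:
    """All index pairs (i, j), i < j, within both tolerances.

    Both boundaries are inclusive (|Δ| ≤ tol).  A ppm tolerance is evaluated
    against the smaller m/z of the pair, which is symmetric and conservative.
    The implementation sorts by m/z and slides a window, so it scales as
    n·log n + output size rather than n²; it is oracle-tested against the
    all-pairs definition.

    Entries with missing iRT can never satisfy the iRT condition; pairs
    involving them are rejected and counted in a warning, never passed.
    """
    order = sorted(range(len(entries)), key=lambda k: entries[k].mz)
    pairs: list[tuple[int, int]] = []
    missing_irt_rejections = 0
    n = len(order)
    for a in range(n):
        ia = order[a]
        ea = entries[ia]
        window = config.mz_tolerance.window(ea.mz)  # ea.mz is the smaller m/z
        for b in range(a + 1, n):
            ib = order[b]
            eb = entries[ib]
            if eb.mz - ea.mz > window:
                break
            if ea.irt is None or eb.irt is None:
                missing_irt_rejections += 1
                continue
            if abs(ea.irt - eb.irt) <= config.irt_tolerance:
                pairs.append((min(ia, ib), max(ia, ib)))
    if missing_irt_rejections:
        logger.warning(
            "rejected %d m/z-compatible pairs because one side lacks an iRT value",
            missing_irt_rejections,
        )
    pairs.sort()
    return pairs
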