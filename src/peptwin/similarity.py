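"""The scoring core: tolerance/ppm peak matching between two spectra and the
three similarity measures built on it.

Peak matching is greedy closest-first, in the spirit of the ``joinPeaks``
routine of the R package *Spectra*: the unmatched candidate pair with the
smallest |Δm/z| inside the combined tolerance is matched, both peaks are
retired, and the process repeats until no candidate remains.  The combined
tolerance is additive, Δ_allowed = tolerance_Da + ppm·1e-6·min(mz_a, mz_b).
Ties on |Δm/z| are broken by the lower index in spectrum A, then B, so
matching is fully deterministic.

Scores:

* ``ndotproduct`` — squared weighted cosine over the outer join of the two
  peak lists (unmatched peaks enter with intensity 0 on the absent side),
  with per-peak weights W = intensity^m · (m/z)^n.
* ``nspectraangle`` — the normalized spectral angle
  NSA = 1 − 2·arccos(C)/π where C is the (unsquared) weighted cosine.
* ``greedy_cosine`` — raw-intensity cosine restricted to matched pairs,
  normalized by the full spectrum norms (the matchms convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .spectra import PeakList

__all__ = [
    "SimilarityConfig",
    "PeakMatch",
    "join_peaks",
    "ndotproduct",
    "nspectraangle",
    "greedy_cosine",
    "score_spectra",
    "METRICS",
    "WEIGHT_PRESETS",
]

#: Named (m, n) weight presets.  m exponentiates intensity, n exponentiates m/z.
WEIGHT_PRESETS: dict[str, tuple[float, float]] = {
    "sqrt": (0.5, 0.0),
    "massbank": (0.5, 2.0),
    "stein-scott": (0.6, 3.0),
}

_METRIC_NAMES = ("ndotproduct", "nspectraangle", "greedy_cosine")


@dataclass(frozen=True)
class SimilarityConfig:
    """Defaults: 10 ppm MS2 match tolerance, square-root intensity weighting,
    normalized spectral angle."""

    match_tolerance: float = 0.0  # Da component of the combined tolerance
    match_ppm: float = 10.0
    weight_m: float = 0.5  # exponent on intensity
    weight_n: float = 0.0  # exponent on m/z
    metric: str = "nspectraangle"

    def __post_init__(self) -> None:
        if self.match_tolerance < 0 or self.match_ppm < 0:
            raise ValueError("match tolerances must be non-negative")
        if self.metric not in _METRIC_NAMES:
            raise ValueError(
                f"unknown metric {self.metric!r}; expected one of {sorted(_METRIC_NAMES)}"
            )

    def with_preset(self, preset: str) -> "SimilarityConfig":
        m, n = WEIGHT_PRESETS[preset]
        return replace(self, weight_m=m, weight_n=n)


@dataclass(frozen=True)
class PeakMatch:
    """Aligned index pairs plus the leftovers on each side."""

    pairs: tuple[tuple[int, int], ...]
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]


def _allowed(mz_a: float, mz_b: float, config: SimilarityConfig) -> float:
    return config.match_tolerance + config.match_ppm * 1e-6 * min(mz_a, mz_b)


def join_peaks(a: PeakList, b: PeakList, config: SimilarityConfig = SimilarityConfig()) -> PeakMatch:
    """Greedy closest-first matching of two sorted peak lists.

    Candidates within the combined tolerance are processed in order of
    ascending (|Δm/z|, index in A, index in B); a candidate is accepted when
    both peaks are still free.  This is equivalent to repeatedly extracting
    the closest remaining candidate, and is deterministic.
    """
    na, nb = len(a), len(b)
    candidates: list[tuple[float, int, int]] = []
    j_lo = 0
    for i in range(na):
        mz_i = a.mz[i]
        # widest possible window at this m/z (min(mz) <= mz_i + allowed)
        max_window = config.match_tolerance + config.match_ppm * 1e-6 * mz_i
        while j_lo < nb and b.mz[j_lo] < mz_i - max_window:
            j_lo += 1
        for j in range(j_lo, nb):
            d = b.mz[j] - mz_i
            if d > max_window:
                break
            if abs(d) <= _allowed(mz_i, b.mz[j], config):
                candidates.append((abs(d), i, j))
    candidates.sort()
    used_a = np.zeros(na, dtype=bool)
    used_b = np.zeros(nb, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _d, i, j in candidates:
        if not used_a[i] and not used_b[j]:
            pairs.append((i, j))
            used_a[i] = True
            used_b[j] = True
    pairs.sort()
    return PeakMatch(
        pairs=tuple(pairs),
        unmatched_a=tuple(int(i) for i in np.flatnonzero(~used_a)),
        unmatched_b=tuple(int(j) for j in np.flatnonzero(~used_b)),
    )


def _outer_join_weights(
    a: PeakList, b: PeakList, match: PeakMatch, config: SimilarityConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Weight vectors over the outer join of the two peak lists.

    W = intensity^m · (m/z)^n, with W = 0 for a zero-filled absent partner
    (regardless of m — an absent peak must carry no weight).  The m/z of the
    present peak supplies the m/z weight for its zero partner.
    """
    rows_mz_a, rows_ia, rows_mz_b, rows_ib = [], [], [], []
    for i, j in match.pairs:
        rows_mz_a.append(a.mz[i]); rows_ia.append(a.intensity[i])
        rows_mz_b.append(b.mz[j]); rows_ib.append(b.intensity[j])
    for i in match.unmatched_a:
        rows_mz_a.append(a.mz[i]); rows_ia.append(a.intensity[i])
        rows_mz_b.append(a.mz[i]); rows_ib.append(0.0)
    for j in match.unmatched_b:
        rows_mz_a.append(b.mz[j]); rows_ia.append(0.0)
        rows_mz_b.append(b.mz[j]); rows_ib.append(b.intensity[j])
    mz_a = np.asarray(rows_mz_a); ia = np.asarray(rows_ia)
    mz_b = np.asarray(rows_mz_b); ib = np.asarray(rows_ib)
    with np.errstate(divide="ignore", invalid="ignore"):
        wa = np.where(ia > 0, ia ** config.weight_m * mz_a ** config.weight_n, 0.0)
        wb = np.where(ib > 0, ib ** config.weight_m * mz_b ** config.weight_n, 0.0)
    return wa, wb


def _weighted_cosine(a: PeakList, b: PeakList, config: SimilarityConfig) -> float:
    if len(a) == 0 or len(b) == 0:
        return 0.0
    match = join_peaks(a, b, config)
    wa, wb = _outer_join_weights(a, b, match, config)
    denom = math.sqrt(float(np.sum(wa**2)) * float(np.sum(wb**2)))
    if denom == 0:
        return 0.0
    c = float(np.dot(wa, wb)) / denom
    return min(max(c, 0.0), 1.0)


def ndotproduct(a: PeakList, b: PeakList, config: SimilarityConfig = SimilarityConfig()) -> float:
    """Normalized dot product: the squared weighted cosine, in [0, 1]."""
    return _weighted_cosine(a, b, config) ** 2


def nspectraangle(a: PeakList, b: PeakList, config: SimilarityConfig = SimilarityConfig()) -> float:
    """Normalized spectral angle: 1 − 2·arccos(cosine)/π, in [0, 1].

    Maps the cosine onto an angular scale with finer resolution near 1,
    which is where indistinguishable-pair thresholds live.
    """
    c = _weighted_cosine(a, b, config)
    return 1.0 - 2.0 * math.acos(c) / math.pi


def greedy_cosine(a: PeakList, b: PeakList, config: SimilarityConfig = SimilarityConfig()) -> float:
    """Cosine over greedily matched pairs with full-spectrum normalization.

    Uses raw intensities (no m/n weighting): score =
    Σ_matched I_a·I_b / (‖I_a‖·‖I_b‖).  Unmatched peaks contribute only to
    the norms.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0
    match = join_peaks(a, b, config)
    num = sum(float(a.intensity[i]) * float(b.intensity[j]) for i, j in match.pairs)
    denom = math.sqrt(float(np.sum(a.intensity**2)) * float(np.sum(b.intensity**2)))
    if denom == 0:
        return 0.0
    return min(num / denom, 1.0)


METRICS: dict[str, Callable[[PeakList, PeakList, SimilarityConfig], float]] = {
    "ndotproduct": ndotproduct,
    "nspectraangle": nspectraangle,
    "greedy_cosine": greedy_cosine,
}


def score_spectra(a: PeakList, b: PeakList, config: SimilarityConfig = SimilarityConfig()) -> float:
    """Dispatch to the configured metric."""
    return METRICS[config.metric](a, b, config)
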