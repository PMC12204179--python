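"""Mirror plots: two fragmentation spectra head-to-head, the second inverted."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .similarity import PeakMatch, SimilarityConfig, join_peaks
from .spectra import PeakList, SpectrumRecord

__all__ = ["mirror_plot"]

_FORMATS = ("png", "svg")

# stable ids + no timestamp so repeated SVG renders are byte-identical
matplotlib.rcParams["svg.hashsalt"] = "peptwin"

_MATCHED = "#c0392b"
_UNMATCHED = "#7f8c8d"


def _as_spectrum(s: Union[SpectrumRecord, PeakList]) -> tuple[PeakList, str]:
    if isinstance(s, SpectrumRecord):
        return s.peaks, s.name
    return s, ""


def mirror_plot(
    a: Union[SpectrumRecord, PeakList],
    b: Union[SpectrumRecord, PeakList],
    path,
    match: Optional[PeakMatch] = None,
    format: Optional[str] = None,
    title: Optional[str] = None,
    normalize: bool = True,
    config: SimilarityConfig = SimilarityConfig(),
) -> Path:
    """Render spectrum ``a`` upward and ``b`` downward into ``path``.

    Matched peaks (from ``match``, or computed with ``config`` when omitted)
    are highlighted; intensities are scaled to base peak = 100 per side
    unless ``normalize`` is off.  Returns the written path.
    """
    peaks_a, name_a = _as_spectrum(a)
    peaks_b, name_b = _as_spectrum(b)
    if len(peaks_a) == 0 or len(peaks_b) == 0:
        raise ValueError("mirror plot requires two non-empty spectra")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown mirror-plot format {fmt!r}; expected {_FORMATS}")
    if match is None:
        match = join_peaks(peaks_a, peaks_b, config)

    ia = peaks_a.intensity * (100.0 / peaks_a.base_peak_intensity() if normalize else 1.0)
    ib = peaks_b.intensity * (100.0 / peaks_b.base_peak_intensity() if normalize else 1.0)
    matched_a = {i for i, _ in match.pairs}
    matched_b = {j for _, j in match.pairs}

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for i, (mz, inten) in enumerate(zip(peaks_a.mz, ia)):
        ax.vlines(mz, 0, inten, color=_MATCHED if i in matched_a else _UNMATCHED,
                  linewidth=1.2)
    for j, (mz, inten) in enumerate(zip(peaks_b.mz, ib)):
        ax.vlines(mz, 0, -inten, color=_MATCHED if j in matched_b else _UNMATCHED,
                  linewidth=1.2)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_xlabel("m/z")
    ax.set_ylabel("relative intensity (%)" if normalize else "intensity")
    if title is None:
        title = f"{name_a}  vs  {name_b}".strip()
    if title:
        ax.set_title(title, fontsize=10)
    ax.text(0.99, 0.97, name_a, transform=ax.transAxes, ha="right", va="top", fontsize=8)
    ax.text(0.99, 0.03, name_b, transform=ax.transAxes, ha="right", va="bottom", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
    plt.close(fig)
    return path
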