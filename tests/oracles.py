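"""Independent brute-force reference implementations used as test oracles.

These transcribe the definitions directly (naive quadratic loops, explicit
formulas) and deliberately share no code with the package internals they
check.
"""

from __future__ import annotations

import math

import numpy as np

from peptwin.spectra import PeakList


def brute_join_peaks(a: PeakList, b: PeakList, tol_da: float, tol_ppm: float):
    """Naive closest-first matching: repeatedly scan ALL unused candidate
    pairs within tolerance and take the smallest |dmz| (ties: lower A index,
    then lower B index)."""
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    while True:
        best = None
        for i in range(len(a)):
            if i in used_a:
                continue
            for j in range(len(b)):
                if j in used_b:
                    continue
                d = abs(float(a.mz[i]) - float(b.mz[j]))
                allowed = tol_da + tol_ppm * 1e-6 * min(float(a.mz[i]), float(b.mz[j]))
                if d <= allowed:
                    key = (d, i, j)
                    if best is None or key < best:
                        best = key
        if best is None:
            break
        _, i, j = best
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    pairs.sort()
    unmatched_a = tuple(i for i in range(len(a)) if i not in used_a)
    unmatched_b = tuple(j for j in range(len(b)) if j not in used_b)
    return tuple(pairs), unmatched_a, unmatched_b


def _aligned_rows(a: PeakList, b: PeakList, tol_da: float, tol_ppm: float):
    """Outer-join rows (mz_a, int_a, mz_b, int_b); absent side has intensity 0
    and borrows the partner's m/z."""
    pairs, unmatched_a, unmatched_b = brute_join_peaks(a, b, tol_da, tol_ppm)
    rows = []
    for i, j in pairs:
        rows.append((float(a.mz[i]), float(a.intensity[i]),
                     float(b.mz[j]), float(b.intensity[j])))
    for i in unmatched_a:
        rows.append((float(a.mz[i]), float(a.intensity[i]), float(a.mz[i]), 0.0))
    for j in unmatched_b:
        rows.append((float(b.mz[j]), 0.0, float(b.mz[j]), float(b.intensity[j])))
    return rows


def _weight(intensity: float, mz: float, m: float, n: float) -> float:
    if intensity <= 0:
        return 0.0
    return intensity**m * mz**n


def brute_cosine(a, b, tol_da, tol_ppm, m, n) -> float:
    if len(a) == 0 or len(b) == 0:
        return 0.0
    rows = _aligned_rows(a, b, tol_da, tol_ppm)
    num = sum(_weight(ia, mza, m, n) * _weight(ib, mzb, m, n)
              for mza, ia, mzb, ib in rows)
    den_a = sum(_weight(ia, mza, m, n) ** 2 for mza, ia, _, _ in rows)
    den_b = sum(_weight(ib, mzb, m, n) ** 2 for _, _, mzb, ib in rows)
    if den_a == 0 or den_b == 0:
        return 0.0
    c = num / math.sqrt(den_a * den_b)
    return min(max(c, 0.0), 1.0)


def brute_ndotproduct(a, b, tol_da, tol_ppm, m, n) -> float:
    return brute_cosine(a, b, tol_da, tol_ppm, m, n) ** 2


def brute_nspectraangle(a, b, tol_da, tol_ppm, m, n) -> float:
    return 1.0 - 2.0 * math.acos(brute_cosine(a, b, tol_da, tol_ppm, m, n)) / math.pi


def brute_greedy_cosine(a, b, tol_da, tol_ppm) -> float:
    if len(a) == 0 or len(b) == 0:
        return 0.0
    pairs, _, _ = brute_join_peaks(a, b, tol_da, tol_ppm)
    num = sum(float(a.intensity[i]) * float(b.intensity[j]) for i, j in pairs)
    den = math.sqrt(float(np.sum(np.asarray(a.intensity) ** 2))
                    * float(np.sum(np.asarray(b.intensity) ** 2)))
    if den == 0:
        return 0.0
    return min(num / den, 1.0)


def brute_candidate_pairs(entries, mz_value, mz_unit, irt_tol):
    """All-pairs definition of grouping: |dmz| <= tol (ppm vs the smaller
    m/z) and |dirt| <= irt_tol, both sides having an iRT."""
    out = []
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            ei, ej = entries[i], entries[j]
            window = mz_value if mz_unit == "Da" else mz_value * 1e-6 * min(ei.mz, ej.mz)
            if abs(ei.mz - ej.mz) > window:
                continue
            if ei.irt is None or ej.irt is None:
                continue
            if abs(ei.irt - ej.irt) <= irt_tol:
                out.append((i, j))
    return out


def brute_tryptic_fragments(sequence: str, before_proline_blocked: bool = True):
    """Base tryptic fragments by direct scanning, independent of the package."""
    cuts = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (before_proline_blocked and sequence[i + 1] == "P"):
            cuts.append(i + 1)
    frags = []
    start = 0
    for c in cuts + [len(sequence)]:
        frags.append(sequence[start:c])
        start = c
    return frags


def brute_missed_cleavage_peptides(fragments: list[str], k: int) -> list[str]:
    """Every union of <= k+1 adjacent base fragments, by direct enumeration."""
    out = []
    for start in range(len(fragments)):
        for end in range(start + 1, min(start + k + 2, len(fragments) + 1)):
            out.append("".join(fragments[start:end]))
    return out
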