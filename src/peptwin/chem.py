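"""Peptide mass chemistry: residue masses, precursor m/z, b/y fragments, ppm arithmetic.

All masses are monoisotopic. Every downstream tolerance in this package is
ppm-scale, so average masses are never used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "RESIDUE_MASS",
    "PROTON",
    "WATER",
    "PeptideIon",
    "FragmentIon",
    "monoisotopic_mass",
    "precursor_mz",
    "theoretical_fragments",
    "ppm_diff",
]

#: Monoisotopic residue (amino-acid minus water) masses in Da for the 20
#: canonical amino acids.  Leucine and isoleucine are exact isomers, and
#: G+Q == A+N (the isobaric pair behind many indistinguishable peptides).
RESIDUE_MASS: dict[str, float] = {
    "G": 57.0214637,
    "A": 71.0371138,
    "S": 87.0320284,
    "P": 97.0527638,
    "V": 99.0684139,
    "T": 101.0476785,
    "C": 103.0091848,
    "L": 113.0840640,
    "I": 113.0840640,
    "N": 114.0429274,
    "D": 115.0269430,
    "Q": 128.0585775,
    "K": 128.0949630,
    "E": 129.0425931,
    "M": 131.0404849,
    "H": 137.0589119,
    "F": 147.0684139,
    "R": 156.1011110,
    "W": 186.0793129,
    "Y": 163.0633285,
}

PROTON = 1.007276466  # Da, mass of a proton
WATER = 18.010565  # Da, monoisotopic mass of H2O

#: Ambiguous / non-canonical one-letter codes that are rejected outright.
NON_CANONICAL = frozenset("BJOUXZ")


class UnknownResidueError(ValueError):
    """A peptide sequence contains a letter outside the canonical 20."""

    def __init__(self, sequence: str, position: int):
        self.sequence = sequence
        self.position = position  # 1-based
        self.residue = sequence[position - 1]
        super().__init__(
            f"unknown residue {self.residue!r} at position {position} "
            f"in sequence {sequence!r}"
        )


def validate_sequence(sequence: str) -> None:
    """Raise :class:`UnknownResidueError` unless every letter is canonical."""
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for i, ch in enumerate(sequence, start=1):
        if ch not in RESIDUE_MASS:
            raise UnknownResidueError(sequence, i)


@dataclass(frozen=True)
class PeptideIon:
    """A peptide precursor ion: sequence, charge and generic modifications.

    Modifications are (1-based position, delta mass in Da) pairs; there is no
    controlled PTM vocabulary here — names and site rules belong to the
    prediction models, not to the mass bookkeeping.
    """

    sequence: str
    charge: int = 2
    modifications: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        object.__setattr__(self, "modifications", tuple(self.modifications))
        for pos, _delta in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside [1, {len(self.sequence)}]"
                )

    @property
    def identifier(self) -> str:
        """Precursor identifier in ``SEQUENCE/charge`` notation."""
        return f"{self.sequence}/{self.charge}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentIon:
    """A backbone fragment: series ('b' retains the N terminus, 'y' the C
    terminus), ordinal (number of residues retained), charge and m/z."""

    series: str
    ordinal: int
    charge: int
    mz: float


def monoisotopic_mass(ion: PeptideIon | str) -> float:
    """Neutral monoisotopic mass in Da: residue sum + water + modification deltas."""
    if isinstance(ion, str):
        ion = PeptideIon(ion, charge=1)
    mass = WATER + sum(RESIDUE_MASS[ch] for ch in ion.sequence)
    mass += sum(delta for _pos, delta in ion.modifications)
    return mass


def precursor_mz(ion: PeptideIon) -> float:
    """Precursor m/z in Th: (M + z·proton) / z."""
    if ion.charge < 1:
        raise ValueError(f"charge must be >= 1, got {ion.charge}")
    return (monoisotopic_mass(ion) + ion.charge * PROTON) / ion.charge


def theoretical_fragments(
    ion: PeptideIon,
    series: Iterable[str] = ("b", "y"),
    max_fragment_charge: int = 1,
) -> list[FragmentIon]:
    """Singly- to ``max_fragment_charge``-charged b/y ions, sorted by m/z.

    b_i = (sum of first i residues + z·proton) / z and
    y_i = (sum of last i residues + water + z·proton) / z, for ordinals
    1..len-1.  Modifications contribute their delta to every fragment whose
    retained residues include the modified position.
    """
    n = len(ion.sequence)
    if n < 2:
        raise ValueError(
            f"peptide {ion.sequence!r} has no backbone fragments (length < 2)"
        )
    series = set(series)
    unknown = series - {"b", "y"}
    if unknown:
        raise ValueError(f"unsupported fragment series: {sorted(unknown)}")
    res = [RESIDUE_MASS[ch] for ch in ion.sequence]
    for pos, delta in ion.modifications:
        res[pos - 1] += delta
    # prefix[i] = mass of the first i residues
    prefix = [0.0]
    for m in res:
        prefix.append(prefix[-1] + m)
    total = prefix[-1]

    out: list[FragmentIon] = []
    for i in range(1, n):
        for z in range(1, max_fragment_charge + 1):
            if "b" in series:
                out.append(FragmentIon("b", i, z, (prefix[i] + z * PROTON) / z))
            if "y" in series:
                out.append(
                    FragmentIon("y", i, z, (total - prefix[n - i] + WATER + z * PROTON) / z)
                )
    out.sort(key=lambda f: (f.mz, f.series, f.ordinal, f.charge))
    return out


def ppm_diff(a: float, b: float) -> float:
    """Signed relative difference of ``a`` vs reference ``b`` in parts per million."""
    if b <= 0:
        raise ValueError(f"reference m/z must be positive, got {b}")
    return (a - b) / b * 1e6
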