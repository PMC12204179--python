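"""In-silico generation of candidate peptides: enzymatic digestion, sliding
windows for immunopeptidomics, single amino-acid variants, and precursor
enumeration over charge states."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .chem import PeptideIon, RESIDUE_MASS, precursor_mz
from .io import ProteinRecord, VariantRecord, dedup_precursors

logger = logging.getLogger(__name__)

__all__ = [
    "EnzymeRule",
    "DigestConfig",
    "ENZYMES",
    "digest",
    "sliding_windows",
    "apply_variants",
    "enumerate_precursors",
]


@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage specificity: cut after ``cleave_after`` unless the next
    residue is in ``suppress_if_next``."""

    name: str
    cleave_after: frozenset
    suppress_if_next: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        object.__setattr__(self, "cleave_after", frozenset(self.cleave_after))
        object.__setattr__(self, "suppress_if_next", frozenset(self.suppress_if_next))

    def cleavage_sites(self, sequence: str) -> list[int]:
        """Positions i such that the bond after ``sequence[i-1]`` is cut
        (0 < i < len)."""
        sites = []
        for i in range(1, len(sequence)):
            if sequence[i - 1] in self.cleave_after and sequence[i] not in self.suppress_if_next:
                sites.append(i)
        return sites


#: Built-in enzymes.  Trypsin and chymotrypsin use the common
#: "no cleavage before proline" rule; pass a custom EnzymeRule to disable it.
ENZYMES: dict[str, EnzymeRule] = {
    "trypsin": EnzymeRule("trypsin", frozenset("KR"), frozenset("P")),
    "trypsin/p": EnzymeRule("trypsin/p", frozenset("KR")),
    "lys-c": EnzymeRule("lys-c", frozenset("K")),
    "chymotrypsin": EnzymeRule("chymotrypsin", frozenset("FWYL"), frozenset("P")),
}


@dataclass(frozen=True)
class DigestConfig:
    """Digestion parameters.  Defaults are the standard tryptic bottom-up
    setup: no missed cleavages, peptide lengths 8–20, charges +2 and +3."""

    enzyme: EnzymeRule = ENZYMES["trypsin"]
    missed_cleavages: int = 0
    min_length: int = 8
    max_length: int = 20
    charges: tuple[int, ...] = (2, 3)

    def __post_init__(self) -> None:
        if isinstance(self.enzyme, str):
            object.__setattr__(self, "enzyme", ENZYMES[self.enzyme.lower()])
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if any(z < 1 for z in self.charges):
            raise ValueError("charges must all be >= 1")
        object.__setattr__(self, "charges", tuple(sorted(self.charges)))


def digest(sequence: str, config: DigestConfig = DigestConfig()) -> list[str]:
    """Cleave ``sequence`` into peptides under ``config``.

    With k missed cleavages every concatenation of up to k+1 adjacent base
    fragments is emitted (shorter spans first), then the length filter is
    applied.  With 0 missed cleavages and no length filter the fragments
    concatenate exactly to the input.
    """
    if not sequence:
        return []
    sites = config.enzyme.cleavage_sites(sequence)
    bounds = [0] + sites + [len(sequence)]
    fragments = [sequence[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
    peptides: list[str] = []
    for span in range(1, config.missed_cleavages + 2):
        for start in range(0, len(fragments) - span + 1):
            pep = "".join(fragments[start : start + span])
            if config.min_length <= len(pep) <= config.max_length:
                peptides.append(pep)
    return peptides


def sliding_windows(sequence: str, lengths: Iterable[int]) -> list[str]:
    """Every contiguous substring of each requested length, left to right.

    Duplicates across windows are retained; deduplication happens at
    precursor enumeration.  Lengths longer than the sequence yield nothing.
    """
    lengths = sorted(set(lengths))
    if any(L < 1 for L in lengths):
        raise ValueError("window lengths must all be >= 1")
    out: list[str] = []
    for L in lengths:
        for i in range(0, len(sequence) - L + 1):
            out.append(sequence[i : i + L])
    return out


def apply_variants(
    protein: ProteinRecord, variants: Sequence[VariantRecord]
) -> list[ProteinRecord]:
    """Expand a protein into its canonical form plus one record per variant.

    Each variant applies exactly one substitution (no combinatorial
    stacking).  Variants whose stated reference residue does not match the
    sequence, or whose position is out of range, are skipped with a warning.
    The canonical record is always first in the output.
    """
    out = [protein]
    for var in variants:
        if var.accession != protein.accession:
            continue
        if var.position > len(protein.sequence):
            logger.warning(
                "%s: variant position %d beyond sequence length %d, skipped",
                protein.accession, var.position, len(protein.sequence),
            )
            continue
        observed = protein.sequence[var.position - 1]
        if observed != var.ref:
            logger.warning(
                "%s: variant %s%d%s reference mismatch (sequence has %s), skipped",
                protein.accession, var.ref, var.position, var.alt, observed,
            )
            continue
        seq = (
            protein.sequence[: var.position - 1]
            + var.alt
            + protein.sequence[var.position :]
        )
        out.append(
            ProteinRecord(
                accession=f"{protein.accession}:{var.ref}{var.position}{var.alt}",
                description=f"{protein.description} variant {var.ref}{var.position}{var.alt}",
                sequence=seq,
            )
        )
    return out


def enumerate_precursors(
    peptides: Iterable[str],
    charges: Sequence[int],
    predict_irt=None,
):
    """Cross peptides with charge states into deduplicated grouping entries.

    Peptides containing non-canonical residues (B, J, O, U, X, Z) are dropped
    with a logged count — prediction models cannot handle them.  Duplicate
    peptides collapse before charge expansion.  ``predict_irt`` maps a list
    of :class:`PeptideIon` to iRT values; if omitted, iRT is left unset.
    """
    from .grouping import PrecursorEntry  # local import: grouping depends on chem only

    seen: set[str] = set()
    clean: list[str] = []
    dropped = 0
    for pep in peptides:
        if pep in seen:
            continue
        seen.add(pep)
        if not pep or any(ch not in RESIDUE_MASS for ch in pep):
            dropped += 1
            continue
        clean.append(pep)
    if dropped:
        logger.warning("dropped %d peptides with non-canonical residues", dropped)

    ions = [PeptideIon(pep, z) for pep in clean for z in sorted(set(charges))]
    ions, _ = dedup_precursors(ions)
    if predict_irt is not None:
        irts = predict_irt(ions)
    else:
        irts = [None] * len(ions)
    return [
        PrecursorEntry(
            identifier=ion.identifier,
            ion=ion,
            mz=precursor_mz(ion),
            irt=irt,
        )
        for ion, irt in zip(ions, irts)
    ]
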