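"""Seeded synthetic data: random proteomes with planted indistinguishable
("twin") peptide pairs and near-miss decoys, so every stage of the pipeline
is testable offline with analytic ground truth.

The planted edits are mass-preserving, which keeps ground truth exact:

* ``adjacent_swap`` — swap two adjacent internal residues (a sequence
  permutation; precursor mass and additive iRT are both unchanged).
* ``il_swap`` — replace one isoleucine by leucine or vice versa (exact
  isomers; spectra are identical).
* ``isobaric_gq_an`` — G→A plus Q→N (or A→G plus N→Q) at nearby positions;
  G+Q and A+N have the same summed residue mass.

Decoys are deamidation-style single edits (N→D or Q→E, Δm ≈ +0.984 Da),
far outside any ppm-scale MS1 tolerance but close enough to be a meaningful
rejection test.  Every planted peptide is spliced into a fresh carrier
protein between tryptic anchor points, so a strict tryptic digest of the
generated FASTA re-emits it exactly.

Realistic proteome composition statistics are a non-goal; residues are
drawn uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import RESIDUE_MASS
from .digestion import DigestConfig, digest
from .io import ProteinRecord, write_fasta
from .spectra import PeakList, SpectrumRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TwinPlantSpec",
    "generate_proteome",
    "write_registry",
    "read_registry",
    "perturb_spectrum",
    "registry_pair_identifiers",
]

_ALPHABET = sorted(RESIDUE_MASS)  # 20 canonical residues
_TWIN_OPS = ("adjacent_swap", "il_swap", "isobaric_gq_an")

REGISTRY_COLUMNS = [
    "kind", "op", "peptide_a", "peptide_b", "carrier_accession", "delta_mass_da",
]


@dataclass(frozen=True)
class TwinPlantSpec:
    """Study conditions for one synthetic proteome.

    ``twin_fraction`` is the fraction of eligible tryptic peptides that get
    a planted mass-preserving twin; ``decoy_fraction`` likewise for
    near-miss decoys.  The seed is mandatory: everything is reproducible.
    """

    n_proteins: int = 200
    min_protein_length: int = 200
    max_protein_length: int = 400
    twin_fraction: float = 0.05
    decoy_fraction: float = 0.02
    ops: tuple[str, ...] = _TWIN_OPS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.twin_fraction <= 1:
            raise ValueError("twin_fraction must lie in [0, 1]")
        if not 0 <= self.decoy_fraction <= 1:
            raise ValueError("decoy_fraction must lie in [0, 1]")
        unknown = set(self.ops) - set(_TWIN_OPS)
        if unknown:
            raise ValueError(f"unknown twin ops: {sorted(unknown)}")
        if self.min_protein_length > self.max_protein_length:
            raise ValueError("min_protein_length must be <= max_protein_length")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def _try_adjacent_swap(pep: str, rng: np.random.Generator) -> Optional[str]:
    # swap positions p, p+1 (0-based) with 1 <= p <= n-3: never touches the
    # termini (the C-terminal K/R anchors the tryptic pattern) and never
    # moves K/R/P, so the carrier's cleavage structure is preserved
    n = len(pep)
    candidates = [
        p for p in range(1, n - 2)
        if pep[p] != pep[p + 1] and pep[p] not in "KRP" and pep[p + 1] not in "KRP"
    ]
    if not candidates:
        return None
    p = int(rng.choice(candidates))
    return pep[:p] + pep[p + 1] + pep[p] + pep[p + 2 :]


def _try_il_swap(pep: str, rng: np.random.Generator) -> Optional[str]:
    positions = [i for i, ch in enumerate(pep) if ch in "IL"]
    if not positions:
        return None
    i = int(rng.choice(positions))
    other = "L" if pep[i] == "I" else "I"
    return pep[:i] + other + pep[i + 1 :]


def _try_isobaric_gq_an(pep: str, rng: np.random.Generator, max_distance: int = 3) -> Optional[str]:
    # G+Q -> A+N (or the reverse) at nearby positions; proximity keeps the
    # two perturbed fragment ladders short, so the planted pair stays above
    # the fallback-score study threshold
    for src1, src2, dst1, dst2 in (("G", "Q", "A", "N"), ("A", "N", "G", "Q")):
        pos1 = [i for i, ch in enumerate(pep) if ch == src1]
        pos2 = [i for i, ch in enumerate(pep) if ch == src2]
        pairs = [
            (i, j) for i in pos1 for j in pos2 if 0 < abs(i - j) <= max_distance
        ]
        if pairs:
            i, j = pairs[int(rng.integers(len(pairs)))]
            out = list(pep)
            out[i], out[j] = dst1, dst2
            return "".join(out)
    return None


_OP_FUNCS = {
    "adjacent_swap": _try_adjacent_swap,
    "il_swap": _try_il_swap,
    "isobaric_gq_an": _try_isobaric_gq_an,
}


def _try_decoy(pep: str, rng: np.random.Generator) -> Optional[tuple[str, float]]:
    # deamidation-style near-miss: N->D or Q->E, delta +0.984016 Da
    positions = [i for i, ch in enumerate(pep) if ch in "NQ"]
    if not positions:
        return None
    i = int(rng.choice(positions))
    alt = "D" if pep[i] == "N" else "E"
    delta = RESIDUE_MASS[alt] - RESIDUE_MASS[pep[i]]
    return pep[:i] + alt + pep[i + 1 :], delta


def _carrier(rng: np.random.Generator, payload: str, index: int) -> ProteinRecord:
    # prefix ends in R, payload starts non-P by eligibility, suffix starts
    # with A: a strict tryptic digest re-emits the payload exactly
    prefix = _random_sequence(rng, 15)
    prefix = prefix[:-1] + "R"
    if prefix[0] == "P":
        prefix = "A" + prefix[1:]
    suffix = "A" + _random_sequence(rng, 14)
    return ProteinRecord(
        accession=f"SYNCARRIER{index:04d}",
        description=f"SYNCARRIER{index:04d} synthetic carrier protein",
        sequence=prefix + payload + suffix,
    )


def generate_proteome(spec: TwinPlantSpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random proteome plus the ground-truth registry of planted pairs.

    Returns ``(proteins, registry)`` where the registry has one row per
    planted twin or decoy (columns: kind, op, peptide_a, peptide_b,
    carrier_accession, delta_mass_da).  Byte-identical across re-runs with
    the same spec.
    """
    rng = np.random.default_rng(spec.seed)
    proteins = [
        ProteinRecord(
            accession=f"SYN{i:04d}",
            description=f"SYN{i:04d} synthetic protein",
            sequence=_random_sequence(
                rng, int(rng.integers(spec.min_protein_length, spec.max_protein_length + 1))
            ),
        )
        for i in range(spec.n_proteins)
    ]

    digest_cfg = DigestConfig()  # strict trypsin, lengths 8-20
    peptide_set: set[str] = set()
    eligible: list[str] = []
    for prot in proteins:
        for pep in digest(prot.sequence, digest_cfg):
            if pep not in peptide_set:
                peptide_set.add(pep)
                # eligible anchors: tryptic C-terminus, no leading proline
                if pep[-1] in "KR" and pep[0] != "P":
                    eligible.append(pep)

    n_twins = int(round(spec.twin_fraction * len(eligible)))
    n_decoys = int(round(spec.decoy_fraction * len(eligible)))
    chosen = rng.choice(len(eligible), size=min(n_twins + n_decoys, len(eligible)),
                        replace=False)
    twin_idx = chosen[:n_twins]
    decoy_idx = chosen[n_twins:]

    rows = []
    carriers: list[ProteinRecord] = []

    def plant(payload: str) -> ProteinRecord:
        carrier = _carrier(rng, payload, len(carriers))
        carriers.append(carrier)
        return carrier

    for k in twin_idx:
        pep = eligible[int(k)]
        op_order = list(rng.permutation(list(spec.ops)))
        twin = None
        op_used = None
        for op in op_order:
            twin = _OP_FUNCS[op](pep, rng)
            if twin is not None and twin != pep and twin not in peptide_set:
                op_used = op
                break
            twin = None
        if twin is None:
            logger.debug("no applicable twin operation for %r, skipped", pep)
            continue
        peptide_set.add(twin)
        carrier = plant(twin)
        rows.append(
            {
                "kind": "twin", "op": op_used,
                "peptide_a": pep, "peptide_b": twin,
                "carrier_accession": carrier.accession, "delta_mass_da": 0.0,
            }
        )

    for k in decoy_idx:
        pep = eligible[int(k)]
        result = _try_decoy(pep, rng)
        if result is None:
            continue
        decoy, delta = result
        if decoy in peptide_set:
            continue
        peptide_set.add(decoy)
        carrier = plant(decoy)
        rows.append(
            {
                "kind": "decoy", "op": "deamidation",
                "peptide_a": pep, "peptide_b": decoy,
                "carrier_accession": carrier.accession, "delta_mass_da": delta,
            }
        )

    registry = pd.DataFrame(rows, columns=REGISTRY_COLUMNS)
    return proteins + carriers, registry


def registry_pair_identifiers(
    registry: pd.DataFrame, charges: Sequence[int] = (2, 3), kind: str = "twin"
) -> set[frozenset]:
    """Planted pairs as ``{SEQ_A/z, SEQ_B/z}`` identifier sets, per charge."""
    pairs = set()
    for row in registry.itertuples():
        if row.kind != kind:
            continue
        for z in charges:
            pairs.add(frozenset({f"{row.peptide_a}/{z}", f"{row.peptide_b}/{z}"}))
    return pairs


def write_registry(registry: pd.DataFrame, path) -> None:
    registry.to_csv(path, sep="\t", index=False)


def read_registry(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_synthetic_study(spec: TwinPlantSpec, output_dir) -> tuple[Path, Path]:
    """Write ``proteome.fasta`` and ``registry.tsv`` for a spec; returns paths."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    proteins, registry = generate_proteome(spec)
    fasta = output_dir / "proteome.fasta"
    reg = output_dir / "registry.tsv"
    write_fasta(proteins, fasta)
    write_registry(registry, reg)
    return fasta, reg


def perturb_spectrum(
    s: SpectrumRecord, mz_jitter_ppm: float, intensity_cv: float, seed: int
) -> SpectrumRecord:
    """Jitter a spectrum: each m/z shifted uniformly within ±jitter ppm, each
    intensity multiplied by a lognormal factor with shape ``intensity_cv``.
    Deterministic given the seed."""
    if mz_jitter_ppm < 0 or intensity_cv < 0:
        raise ValueError("jitter and cv must be non-negative")
    rng = np.random.default_rng(seed)
    mz = s.peaks.mz * (1.0 + rng.uniform(-mz_jitter_ppm, mz_jitter_ppm, len(s.peaks)) * 1e-6)
    if intensity_cv > 0:
        factors = rng.lognormal(mean=0.0, sigma=intensity_cv, size=len(s.peaks))
    else:
        factors = np.ones(len(s.peaks))
    return s.with_peaks(PeakList(mz, s.peaks.intensity * factors))
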