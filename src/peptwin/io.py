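"""File formats: FASTA proteomes, peptide-list TSVs, spectral libraries
(MGF / NIST-style MSP / long-format TSV), variant tables and result tables.

Spectral-library dialects (documented in the README):

* **MGF** — ``BEGIN IONS``/``END IONS`` blocks with ``TITLE``, ``PEPMASS``,
  ``CHARGE`` (``2+`` and ``2`` both accepted), optional ``RTINSECONDS``
  (stored as minutes, flagged as empirical RT), and the tool-specific keys
  ``SEQ`` and ``IRT`` (predicted, dimensionless).  Parsed with pyteomics.
* **MSP** — ``Name: SEQUENCE/charge``, ``PrecursorMZ:``, ``Comment:`` with an
  ``iRT=`` token, ``Num peaks:`` followed by ``m/z<TAB>intensity`` lines.
* **TSV** — long format, one row per peak, columns
  ``name  sequence  precursor_mz  charge  irt  mz  intensity``.

Missing optional fields are left unset, never defaulted to zero, and every
peak list is sorted ascending by m/z on load.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _mgf

from .chem import PeptideIon, validate_sequence
from .spectra import PeakList, SpectrumRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "VariantRecord",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_peptide_list",
    "write_peptide_list",
    "read_variant_table",
    "read_spectral_library",
    "write_spectral_library",
    "dedup_precursors",
    "write_pairs_table",
    "read_pairs_table",
    "PAIR_TABLE_COLUMNS",
]


class ParseError(ValueError):
    """A file violated its format contract; message carries file/line context."""


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("protein accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.accession}: empty sequence")


@dataclass(frozen=True)
class VariantRecord:
    """A single amino-acid variant: ``ref`` at 1-based ``position`` → ``alt``."""

    accession: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant position must be >= 1, got {self.position}")
        validate_sequence(self.ref)
        validate_sequence(self.alt)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA proteome; one record per header, wrapped lines joined."""
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path.name}:{lineno}: sequence data before any '>' header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace(" ", "").upper()
        records.append(
            ProteinRecord(accession=rec.id, description=rec.description, sequence=seq)
        )
    if not records:
        logger.warning("%s: FASTA file contained no records", path)
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for p in proteins:
            header = p.description if p.description else p.accession
            if not header.startswith(p.accession):
                header = f"{p.accession} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Peptide lists and variant tables
# ---------------------------------------------------------------------------

def read_peptide_list(path, charges: Sequence[int] = (2, 3)) -> list[PeptideIon]:
    """Read a peptide-list TSV into ions.

    Requires a ``sequence`` (or ``peptide``) column.  If a ``charge`` column
    is present, one ion per row; otherwise each row is expanded over
    ``charges``.  Rows with non-canonical residues are dropped and counted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    seq_col = cols.get("sequence") or cols.get("peptide")
    if seq_col is None:
        raise ParseError(
            f"{path.name}: no 'sequence' column; available columns: {list(df.columns)}"
        )
    charge_col = cols.get("charge")
    ions: list[PeptideIon] = []
    dropped = 0
    for _, row in df.iterrows():
        seq = str(row[seq_col]).strip()
        row_charges = (
            [int(row[charge_col])] if charge_col is not None else list(charges)
        )
        try:
            validate_sequence(seq)
        except ValueError as exc:
            dropped += 1
            logger.warning("%s: dropped peptide %r (%s)", path.name, seq, exc)
            continue
        for z in row_charges:
            ions.append(PeptideIon(seq, z))
    if dropped:
        logger.warning("%s: dropped %d invalid peptide rows", path.name, dropped)
    return ions


def write_peptide_list(ions: Iterable[PeptideIon], path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sequence", "charge"])
        for ion in ions:
            writer.writerow([ion.sequence, ion.charge])


def read_variant_table(path) -> list[VariantRecord]:
    """TSV with columns ``accession, position (1-based), ref, alt``."""
    df = pd.read_csv(path, sep="\t")
    required = {"accession", "position", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"variant table missing columns: {sorted(missing)}")
    return [
        VariantRecord(str(r.accession), int(r.position), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Spectral libraries
# ---------------------------------------------------------------------------

_FORMATS = ("mgf", "msp", "tsv")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown spectral-library format {fmt!r}; expected {_FORMATS}")
    return fmt


def read_spectral_library(path, format: Optional[str] = None) -> list[SpectrumRecord]:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mgf":
        return _read_mgf(path)
    if fmt == "msp":
        return _read_msp(path)
    return _read_tsv_library(path)


def write_spectral_library(
    records: Iterable[SpectrumRecord], path, format: Optional[str] = None
) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    records = list(records)
    if fmt == "mgf":
        _write_mgf(records, path)
    elif fmt == "msp":
        _write_msp(records, path)
    else:
        _write_tsv_library(records, path)


def _read_mgf(path: Path) -> list[SpectrumRecord]:
    out: list[SpectrumRecord] = []
    with _mgf.MGF(str(path)) as reader:
        for idx, spec in enumerate(reader):
            params = spec.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                logger.warning("%s: spectrum #%d missing PEPMASS, skipped", path.name, idx)
                continue
            charge = None
            if params.get("charge"):
                charge = int(params["charge"][0])
            retention = None
            kind = None
            if "irt" in params:
                retention, kind = float(params["irt"]), "irt"
            elif "rtinseconds" in params:
                retention, kind = float(params["rtinseconds"]) / 60.0, "minutes"
            out.append(
                SpectrumRecord(
                    name=params.get("title", f"spectrum_{idx}"),
                    precursor_mz=float(pepmass[0]),
                    charge=charge,
                    sequence=params.get("seq"),
                    retention=retention,
                    retention_kind=kind,
                    peaks=PeakList(spec["m/z array"], spec["intensity array"]),
                )
            )
    return out


def _write_mgf(records: list[SpectrumRecord], path: Path) -> None:
    spectra = []
    for rec in records:
        params: dict = {"title": rec.name, "pepmass": rec.precursor_mz}
        if rec.charge is not None:
            params["charge"] = rec.charge
        if rec.sequence is not None:
            params["seq"] = rec.sequence
        if rec.retention is not None:
            if rec.retention_kind == "minutes":
                params["rtinseconds"] = rec.retention * 60.0
            else:
                params["irt"] = rec.retention
        spectra.append(
            {
                "m/z array": rec.peaks.mz,
                "intensity array": rec.peaks.intensity,
                "params": params,
            }
        )
    _mgf.write(spectra, str(path), file_mode="w")


def _read_msp(path: Path) -> list[SpectrumRecord]:
    out: list[SpectrumRecord] = []
    name = None
    fields: dict = {}
    mzs: list[float] = []
    ints: list[float] = []
    declared: Optional[int] = None

    def flush(lineno: int) -> None:
        nonlocal name, fields, mzs, ints, declared
        if name is None:
            return
        if declared is not None and declared != len(mzs):
            logger.warning(
                "%s: record %r declares %d peaks but has %d",
                path.name, name, declared, len(mzs),
            )
        precursor = fields.get("precursormz") or fields.get("mw")
        if precursor is None:
            logger.warning("%s: record %r missing precursor m/z, skipped", path.name, name)
        else:
            sequence = charge = None
            if "/" in name:
                seq_part, _, z_part = name.rpartition("/")
                if z_part.isdigit():
                    sequence, charge = seq_part, int(z_part)
            irt = fields.get("irt")
            out.append(
                SpectrumRecord(
                    name=name,
                    precursor_mz=float(precursor),
                    charge=charge,
                    sequence=sequence,
                    retention=float(irt) if irt is not None else None,
                    retention_kind="irt" if irt is not None else None,
                    peaks=PeakList(mzs, ints),
                )
            )
        name, fields, mzs, ints, declared = None, {}, [], [], None

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush(lineno)
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key = key.strip().lower()
                value = value.strip()
                if key == "name":
                    flush(lineno)
                    name = value
                elif key == "num peaks":
                    declared = int(value)
                elif key == "comment":
                    for token in value.split():
                        if token.lower().startswith("irt="):
                            fields["irt"] = token.split("=", 1)[1]
                else:
                    fields[key] = value
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                mzs.append(float(parts[0]))
                ints.append(float(parts[1]))
            except (IndexError, ValueError) as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: unparseable peak line in record "
                    f"{name!r}: {line!r}"
                ) from exc
        flush(-1)
    return out


def _write_msp(records: list[SpectrumRecord], path: Path) -> None:
    with path.open("w") as fh:
        for rec in records:
            fh.write(f"Name: {rec.name}\n")
            fh.write(f"PrecursorMZ: {rec.precursor_mz:.6f}\n")
            if rec.retention is not None and rec.retention_kind == "irt":
                fh.write(f"Comment: iRT={rec.retention:.4f}\n")
            fh.write(f"Num peaks: {len(rec.peaks)}\n")
            for mz, inten in zip(rec.peaks.mz, rec.peaks.intensity):
                fh.write(f"{mz:.6f}\t{inten:.6f}\n")
            fh.write("\n")


_TSV_COLUMNS = ["name", "sequence", "precursor_mz", "charge", "irt", "mz", "intensity"]


def _read_tsv_library(path: Path) -> list[SpectrumRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "precursor_mz", "mz", "intensity"} - set(df.columns)
    if missing:
        raise ParseError(f"{path.name}: TSV library missing columns {sorted(missing)}")
    out: list[SpectrumRecord] = []
    for name, grp in df.groupby("name", sort=False):
        first = grp.iloc[0]
        if pd.isna(first["precursor_mz"]):
            logger.warning("%s: record %r missing precursor m/z, skipped", path.name, name)
            continue
        charge = None if "charge" not in grp or pd.isna(first.get("charge")) else int(first["charge"])
        seq = None if "sequence" not in grp or pd.isna(first.get("sequence")) else str(first["sequence"])
        irt = None if "irt" not in grp or pd.isna(first.get("irt")) else float(first["irt"])
        out.append(
            SpectrumRecord(
                name=str(name),
                precursor_mz=float(first["precursor_mz"]),
                charge=charge,
                sequence=seq,
                retention=irt,
                retention_kind="irt" if irt is not None else None,
                peaks=PeakList(grp["mz"].to_numpy(), grp["intensity"].to_numpy()),
            )
        )
    return out


def _write_tsv_library(records: list[SpectrumRecord], path: Path) -> None:
    rows = []
    for rec in records:
        for mz, inten in zip(rec.peaks.mz, rec.peaks.intensity):
            rows.append(
                {
                    "name": rec.name,
                    "sequence": rec.sequence,
                    "precursor_mz": rec.precursor_mz,
                    "charge": rec.charge,
                    "irt": rec.retention if rec.retention_kind == "irt" else None,
                    "mz": mz,
                    "intensity": inten,
                }
            )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Precursor deduplication
# ---------------------------------------------------------------------------

def dedup_precursors(entries: Sequence) -> tuple[list, int]:
    """Drop duplicate precursors, keeping the first occurrence.

    The uniqueness key is (sequence, charge, modification set).  Accepts
    :class:`~peptwin.chem.PeptideIon` objects or anything exposing an
    ``.ion`` attribute (e.g. grouping entries).  Returns (unique, n_dropped).
    """
    seen = set()
    unique = []
    dropped = 0
    for entry in entries:
        ion = getattr(entry, "ion", entry)
        key = (ion.sequence, ion.charge, frozenset(ion.modifications))
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        unique.append(entry)
    return unique, dropped


# ---------------------------------------------------------------------------
# Pair tables
# ---------------------------------------------------------------------------

PAIR_TABLE_COLUMNS = [
    "peptide_a", "charge_a", "peptide_b", "charge_b",
    "mz_a", "mz_b", "ppm_diff", "irt_a", "irt_b", "irt_diff",
    "score", "metric",
]


def _split_identifier(identifier: str) -> tuple[str, Optional[int]]:
    seq, _, z = identifier.rpartition("/")
    if z.isdigit():
        return seq, int(z)
    return identifier, None


def write_pairs_table(scores: Sequence, path, format: Optional[str] = None) -> None:
    """Write scored pairs as CSV/TSV/XLSX (format inferred from the suffix).

    One row per pair; re-reading the CSV reproduces the scores to 6 decimals.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("csv", "tsv", "xlsx"):
        raise ValueError(f"unknown pair-table format {format!r}")
    rows = []
    for s in scores:
        pep_a, z_a = _split_identifier(s.id_a)
        pep_b, z_b = _split_identifier(s.id_b)
        rows.append(
            {
                "peptide_a": pep_a, "charge_a": z_a,
                "peptide_b": pep_b, "charge_b": z_b,
                "mz_a": round(s.mz_a, 6), "mz_b": round(s.mz_b, 6),
                "ppm_diff": round(s.ppm_diff, 6),
                "irt_a": round(s.irt_a, 6), "irt_b": round(s.irt_b, 6),
                "irt_diff": round(s.irt_diff, 6),
                "score": round(s.score, 6), "metric": s.metric,
            }
        )
    df = pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        df.to_excel(path, index=False, engine="openpyxl")


def read_pairs_table(path, format: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "csv":
        return pd.read_csv(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "xlsx":
        return pd.read_excel(path, engine="openpyxl")
    raise ValueError(f"unknown pair-table format {format!r}")
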