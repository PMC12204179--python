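"""End-to-end twin analysis: score candidate pairs, call indistinguishable
pairs at a threshold, cluster them into peptide groups, summarize, and write
the result tables plus a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import networkx as nx

from . import __version__
from .chem import ppm_diff
from .digestion import DigestConfig, digest, enumerate_precursors
from .grouping import GroupingConfig, PrecursorEntry, candidate_pairs
from .io import (
    read_fasta,
    read_peptide_list,
    read_spectral_library,
    write_pairs_table,
)
from .prediction import FallbackPredictor, PredictionConfig, Predictor
from .similarity import SimilarityConfig, score_spectra
from .spectra import SpectrumRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PairScore",
    "PeptideGroup",
    "PipelineConfig",
    "score_pairs",
    "indistinguishable_pairs",
    "peptide_groups",
    "summarize",
    "run_twin_analysis",
]


@dataclass(frozen=True)
class PairScore:
    """One scored precursor pair, canonically ordered so id_a < id_b."""

    id_a: str
    id_b: str
    mz_a: float
    mz_b: float
    ppm_diff: float
    irt_a: float
    irt_b: float
    irt_diff: float
    score: float
    metric: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass(frozen=True)
class PeptideGroup:
    """A maximal set of precursors connected by indistinguishable pairs —
    the peptide-level analogue of a protein group."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(sorted(self.members)))
        if len(self.members) < 2:
            raise ValueError("a peptide group needs at least 2 members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a twin run needs.  The defaults are the standard tryptic
    study setup: trypsin / 0 missed cleavages / lengths 8–20 / charges +2,+3,
    NCE 30, 10 ppm MS1, ±5 iRT, 10 ppm MS2, normalized spectral angle at a
    0.7 threshold."""

    digestion: DigestConfig = field(default_factory=DigestConfig)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    grouping: GroupingConfig = field(default_factory=GroupingConfig)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    score_threshold: float = 0.7
    max_pairs_per_precursor: Optional[int] = None  # guard for dense m/z regions

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score threshold must lie in [0, 1]")


class MissingSpectrumError(KeyError):
    """A grouped precursor has no spectrum to score."""


def score_pairs(
    entries: Sequence[PrecursorEntry],
    spectra: Union[Sequence[SpectrumRecord], Mapping[str, SpectrumRecord]],
    config: PipelineConfig = PipelineConfig(),
) -> list[PairScore]:
    """Score every candidate pair with the configured metric.

    ``spectra`` is either aligned 1:1 with ``entries`` or a mapping from
    precursor identifier to spectrum.  A grouped precursor without a
    spectrum raises :class:`MissingSpectrumError` naming the identifier.
    """
    if isinstance(spectra, Mapping):
        by_id = dict(spectra)
    else:
        if len(spectra) != len(entries):
            raise ValueError(
                f"{len(entries)} entries but {len(spectra)} spectra; "
                "they must align 1:1"
            )
        by_id = {e.identifier: s for e, s in zip(entries, spectra)}

    pairs = candidate_pairs(entries, config.grouping)

    if config.max_pairs_per_precursor is not None:
        counts: dict[int, int] = {}
        kept = []
        dropped = 0
        for i, j in pairs:
            if (
                counts.get(i, 0) >= config.max_pairs_per_precursor
                or counts.get(j, 0) >= config.max_pairs_per_precursor
            ):
                dropped += 1
                continue
            counts[i] = counts.get(i, 0) + 1
            counts[j] = counts.get(j, 0) + 1
            kept.append((i, j))
        if dropped:
            logger.warning(
                "pair-explosion guard dropped %d candidate pairs beyond "
                "%d per precursor — results are partial in dense m/z regions",
                dropped, config.max_pairs_per_precursor,
            )
        pairs = kept

    scores: list[PairScore] = []
    for i, j in pairs:
        ea, eb = entries[i], entries[j]
        if ea.identifier > eb.identifier:
            ea, eb = eb, ea
        for e in (ea, eb):
            if e.identifier not in by_id:
                raise MissingSpectrumError(
                    f"no spectrum for grouped precursor {e.identifier!r}"
                )
        value = score_spectra(
            by_id[ea.identifier].peaks, by_id[eb.identifier].peaks, config.similarity
        )
        scores.append(
            PairScore(
                id_a=ea.identifier,
                id_b=eb.identifier,
                mz_a=ea.mz,
                mz_b=eb.mz,
                ppm_diff=ppm_diff(ea.mz, eb.mz),
                irt_a=ea.irt,
                irt_b=eb.irt,
                irt_diff=ea.irt - eb.irt,
                score=value,
                metric=config.similarity.metric,
            )
        )
    scores.sort(key=lambda s: (s.id_a, s.id_b))
    return scores


def indistinguishable_pairs(
    scores: Sequence[PairScore], threshold: float = 0.7
) -> list[PairScore]:
    """Pairs at or above the similarity threshold (inclusive boundary)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [s for s in scores if s.score >= threshold]


def peptide_groups(pairs: Sequence[PairScore]) -> list[PeptideGroup]:
    """Connected components of the indistinguishable-pair graph.

    Singletons cannot occur (every node is an endpoint of some pair).
    Groups are sorted by size descending, then lexicographically.
    """
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.id_a, p.id_b)
    groups = [PeptideGroup(tuple(c)) for c in nx.connected_components(graph)]
    groups.sort(key=lambda g: (-len(g), g.members))
    return groups


def summarize(
    entries: Sequence[PrecursorEntry],
    pairs: Sequence[PairScore],
    groups: Sequence[PeptideGroup],
) -> dict:
    """Headline counts: total precursors, how many are indistinguishable
    from at least one other, and the group structure."""
    involved = sorted({p.id_a for p in pairs} | {p.id_b for p in pairs})
    total = len(entries)
    histogram: dict[int, int] = {}
    for g in groups:
        histogram[len(g)] = histogram.get(len(g), 0) + 1
    return {
        "n_precursors": total,
        "n_indistinguishable_precursors": len(involved),
        "fraction_indistinguishable": (len(involved) / total) if total else 0.0,
        "n_pairs": len(pairs),
        "n_groups": len(groups),
        "group_size_histogram": {str(k): v for k, v in sorted(histogram.items())},
    }


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _detect_input_kind(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fasta", ".fa", ".faa"):
        return "fasta"
    if suffix in (".mgf", ".msp"):
        return "library"
    if suffix in (".tsv", ".txt"):
        header = path.open().readline().lower()
        if "\tmz\t" in header or header.rstrip().endswith("\tintensity"):
            return "library"
        return "peptides"
    raise ValueError(f"cannot infer input kind from suffix {suffix!r} of {path.name}")


def _entries_from_library(records: Sequence[SpectrumRecord]) -> list[PrecursorEntry]:
    kinds = {r.retention_kind for r in records if r.retention is not None}
    if len(kinds) > 1:
        raise ValueError(
            f"library mixes retention kinds {sorted(kinds)}; grouping needs one "
            "consistent kind (predicted iRT or empirical minutes)"
        )
    return [
        PrecursorEntry(identifier=r.name, mz=r.precursor_mz, irt=r.retention)
        for r in records
    ]


def run_twin_analysis(
    input_path,
    config: PipelineConfig = PipelineConfig(),
    output_dir=".",
    predictor: Optional[Predictor] = None,
    input_kind: str = "auto",
    table_format: str = "csv",
    n_plots: int = 0,
) -> dict:
    """Run import → (digest) → predict → group → score → threshold → groups.

    FASTA inputs are digested; peptide lists skip digestion; spectral
    libraries additionally skip prediction and are scored as imported.
    Outputs (pair table, summary JSON, manifest JSON, optional mirror plots)
    land in ``output_dir``; partial outputs are removed on failure.  Returns
    the manifest dict.
    """
    input_path = Path(input_path)
    if not input_path.exists():
        raise FileNotFoundError(f"input file not found: {input_path}")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    if input_kind == "auto":
        input_kind = _detect_input_kind(input_path)
    predictor = predictor or FallbackPredictor()

    created: list[Path] = []
    try:
        if input_kind == "fasta":
            proteins = read_fasta(input_path)
            peptides = [
                pep for prot in proteins for pep in digest(prot.sequence, config.digestion)
            ]
            entries = enumerate_precursors(
                peptides,
                config.digestion.charges,
                lambda ions: predictor.predict_irt(ions, config.prediction),
            )
            spectra = predictor.predict_spectra(
                [e.ion for e in entries], config.prediction
            )
        elif input_kind == "peptides":
            ions = read_peptide_list(input_path, charges=config.digestion.charges)
            entries = enumerate_precursors(
                [i.sequence for i in ions],
                sorted({i.charge for i in ions}),
                lambda batch: predictor.predict_irt(batch, config.prediction),
            )
            spectra = predictor.predict_spectra(
                [e.ion for e in entries], config.prediction
            )
        elif input_kind == "library":
            records = read_spectral_library(input_path)
            records, n_dup = _dedup_records(records)
            if n_dup:
                logger.info("removed %d duplicate library records", n_dup)
            entries = _entries_from_library(records)
            spectra = records
        else:
            raise ValueError(f"unknown input kind {input_kind!r}")

        scores = score_pairs(entries, spectra, config)
        twins = indistinguishable_pairs(scores, config.score_threshold)
        groups = peptide_groups(twins)
        summary = summarize(entries, twins, groups)

        pairs_path = output_dir / f"pairs.{table_format}"
        write_pairs_table(twins, pairs_path, format=table_format)
        created.append(pairs_path)

        summary_path = output_dir / "summary.json"
        groups_payload = [list(g.members) for g in groups]
        summary_path.write_text(
            json.dumps({"summary": summary, "groups": groups_payload},
                       indent=2, sort_keys=True) + "\n"
        )
        created.append(summary_path)

        plot_paths: list[str] = []
        if n_plots > 0:
            from .viz import mirror_plot  # deferred: pulls in matplotlib

            by_id = {s.name: s for s in spectra}
            best = sorted(twins, key=lambda s: -s.score)[:n_plots]
            for rank, pair in enumerate(best, start=1):
                plot_path = output_dir / f"mirror_{rank:02d}.svg"
                mirror_plot(
                    by_id[pair.id_a], by_id[pair.id_b], path=plot_path,
                    title=f"{pair.id_a} vs {pair.id_b}  {pair.metric}={pair.score:.4f}",
                )
                created.append(plot_path)
                plot_paths.append(plot_path.name)

        manifest = {
            "tool": "peptwin",
            "version": __version__,
            "input": {
                "path": str(input_path),
                "kind": input_kind,
                "sha256": _sha256(input_path),
            },
            "config": asdict(config),
            "outputs": {
                "pairs_table": pairs_path.name,
                "summary": summary_path.name,
                "plots": plot_paths,
            },
            "summary": summary,
        }
        manifest_path = output_dir / "manifest.json"
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n"
        )
        return manifest
    except Exception:
        for path in created:
            path.unlink(missing_ok=True)
        raise


def _json_default(obj):
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dedup_records(records: Sequence[SpectrumRecord]) -> tuple[list[SpectrumRecord], int]:
    seen: set[str] = set()
    unique = []
    dropped = 0
    for rec in records:
        if rec.name in seen:
            dropped += 1
            continue
        seen.add(rec.name)
        unique.append(rec)
    return unique, dropped
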