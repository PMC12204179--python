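# peptwin

**peptwin** finds *indistinguishable peptide precursors* — "peptide twins" —
in a proteome or peptide list: pairs of peptide ions that share precursor
m/z (within a ppm-scale MS1 tolerance), elute together (within an iRT
tolerance), and produce fragmentation spectra so similar that no search
engine can tell them apart. Knowing which peptides are twins of something
else delineates the non-addressable part of a search space, which matters
when picking targets in immunopeptidomics, metaproteomics, proteogenomics
and targeted assay design.

## What it computes

For every pair of candidate precursors the tool compares predicted (or
imported) fragmentation spectra. Peaks of two spectra are matched greedily,
closest Δm/z first, within an additive tolerance
`Δ_allowed = tol_Da + ppm·10⁻⁶·min(m/z)`. Three similarity scores are
available, all on [0, 1]:

- **Normalized dot product (NDP)** — squared weighted cosine over the outer
  join of the peak lists, with per-peak weights `W = I^m · (m/z)^n`
  (defaults m = 0.5, n = 0; MassBank m = 0.5, n = 2 and Stein–Scott
  m = 0.6, n = 3 presets included):
  `NDP = (Σ W_a W_b)² / (Σ W_a² · Σ W_b²)`.
- **Normalized spectral angle (NSA)** — `NSA = 1 − 2·arccos(C)/π` where `C`
  is the (unsquared) weighted cosine. This is the default metric; 0.7 is
  the conventional call threshold with real intensity predictions.
- **Greedy cosine** — raw-intensity cosine over the matched pairs,
  normalized by the full spectrum norms.

Pairs scoring at or above the threshold are *indistinguishable pairs*;
their transitive closure (connected components of the pair graph) gives
*peptide groups*, the peptide-level analogue of protein groups.

The full pipeline is: FASTA import → in-silico digestion (trypsin, Lys-C,
chymotrypsin; or sliding windows for immunopeptidomics; optional single
amino-acid variants) → spectrum + iRT prediction → m/z+iRT grouping →
pair scoring → thresholding → group clustering → tables, summary and
mirror plots. Prediction is pluggable: a client for a Koina-style remote
inference service (e.g. `Prosit_2020_intensity_HCD` at NCE 30), or a
deterministic offline fallback (singly charged b/y ladders with a linear
intensity ramp and additive Kyte–Doolittle iRT) that exists to make every
stage runnable and testable without a network — it is **not** a model of
real fragmentation chemistry.

## Worked example

The quartet `IAAELGQR / LAAELANR / LAAELNAR / LAAENALR` (all at charge +2)
is a textbook peptide group: the last three are sequence permutations of
each other, and the first swaps I↔L and G+Q↔A+N — both mass-preserving.

```python
from peptwin import PipelineConfig, score_pairs, indistinguishable_pairs, peptide_groups
from peptwin.digestion import enumerate_precursors
from peptwin.prediction import FallbackPredictor

quartet = ["IAAELGQR", "LAAELANR", "LAAELNAR", "LAAENALR"]
fp = FallbackPredictor()
entries = enumerate_precursors(quartet, (2,), fp.predict_irt)
for e in entries:
    print(f"{e.identifier:12s}  m/z {e.mz:.6f}  iRT {e.irt:+.1f}")

spectra = {e.identifier: fp.predict_spectrum(e.ion) for e in entries}
scores = score_pairs(entries, spectra, PipelineConfig())
for s in scores:
    print(f"{s.id_a:12s} {s.id_b:12s} dppm {s.ppm_diff:+.4f}  dirt {s.irt_diff:+.2f}  NSA {s.score:.4f}")

groups = peptide_groups(indistinguishable_pairs(scores, 0.5))
print("groups:", [g.members for g in groups])
```

prints

```
IAAELGQR/2    m/z 429.245609  iRT -0.0
LAAELANR/2    m/z 429.245609  iRT +1.5
LAAELNAR/2    m/z 429.245609  iRT +1.5
LAAENALR/2    m/z 429.245609  iRT +1.5
IAAELGQR/2   LAAELANR/2   dppm +0.0000  dirt -1.50  NSA 0.6862
IAAELGQR/2   LAAELNAR/2   dppm +0.0000  dirt -1.50  NSA 0.6862
IAAELGQR/2   LAAENALR/2   dppm +0.0000  dirt -1.50  NSA 0.5399
LAAELANR/2   LAAELNAR/2   dppm +0.0000  dirt +0.00  NSA 0.6862
LAAELANR/2   LAAENALR/2   dppm +0.0000  dirt +0.00  NSA 0.5399
LAAELNAR/2   LAAENALR/2   dppm +0.0000  dirt +0.00  NSA 0.5399
groups: [('IAAELGQR/2', 'LAAELANR/2', 'LAAELNAR/2', 'LAAENALR/2')]
```

All four precursors share an identical m/z (0.0 ppm apart) and sit within
the ±5 iRT window, so all six pairs are scored; at the threshold
calibrated for the crude offline predictor (0.5 — see `docs/methods.md`)
the six links fuse the quartet into a single peptide group of four. With a
real intensity model these spectra are near-identical and clear the
conventional 0.7 threshold.

## Command line

```bash
peptwin fixtures -o demo --seed 1            # synthetic proteome + ground truth
peptwin twins demo/proteome.fasta -o out --threshold 0.5 --plots 3
peptwin digest proteome.fasta -o peptides.tsv
peptwin predict peptides.tsv -o library.msp  # offline fallback, or --koina-url
peptwin score libA.mgf libB.mgf -o scores.csv --metric greedy_cosine
peptwin plot library.msp -o mirror.svg
```

`twins` writes `pairs.csv` (or `.tsv`/`.xlsx`), `summary.json` and a
`manifest.json` recording every resolved parameter plus the input checksum;
runs are byte-for-byte reproducible. Flags beat a `--config` YAML file,
which beats the built-in defaults (trypsin, 0 missed cleavages, lengths
8–20, charges +2/+3, NCE 30, 10 ppm MS1, ±5 iRT, 10 ppm MS2, NSA,
threshold 0.7).

### File dialects

- **Peptide list (TSV)**: a `sequence` column, optional `charge` column;
  rows without a charge are expanded over the configured charges.
- **Spectral library TSV** (long format): columns
  `name sequence precursor_mz charge irt mz intensity`, one row per peak.
- **MGF**: `TITLE`, `PEPMASS`, `CHARGE`, optional `RTINSECONDS` (stored as
  empirical minutes, never mixed with iRT), plus `SEQ` and `IRT` keys.
- **MSP**: `Name: SEQUENCE/charge`, `PrecursorMZ:`, `Comment: iRT=…`,
  `Num peaks:` then `m/z<TAB>intensity` lines.
- **Variant table (TSV)**: `accession position ref alt` (1-based position).

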