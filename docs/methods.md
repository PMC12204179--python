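# Methods

This note documents the models, conventions and numerical choices behind
peptwin, and what its synthetic studies do and do not demonstrate.

## Mass chemistry

All masses are monoisotopic; every tolerance in the tool is ppm-scale, so
average masses would be meaningless here. Residue masses are stored to
seven decimals (standard monoisotopic values), which keeps the two
identities that generate most indistinguishable peptides exact at double
precision: mass(I) = mass(L), and mass(G) + mass(Q) = mass(A) + mass(N).
Constants: proton 1.007276466 Da, water 18.010565 Da. Precursor m/z is
(M + z·p)/z; fragments are the standard HCD b/y series, b_i = (Σ first i
residues + z·p)/z and y_i = (Σ last i residues + H₂O + z·p)/z. The a/c/x/z
series, neutral losses and isotope envelopes are out of scope. Modifications
are generic (position, Δmass) pairs with no controlled vocabulary — site
chemistry belongs to the prediction models, not to mass bookkeeping.
Non-canonical letters (B, J, O, U, X, Z) are rejected at ion construction;
digestion products containing them are dropped with a logged count, because
no intensity predictor accepts them.

## Digestion and candidate generation

An enzyme is (cleave-after set, suppress-if-next set). Built-ins: trypsin
(after K/R, not before P), `trypsin/p` (no proline suppression), Lys-C
(after K), chymotrypsin (high-specificity F/W/Y/L, not before P). The
proline rule is a genuine ambiguity in the field; both tryptic variants are
provided and the default (suppressing) is stated everywhere it matters.
With k missed cleavages the tool emits every concatenation of ≤ k+1
adjacent base fragments, shorter spans first; with k = 0 and no length
filter the fragments concatenate exactly to the protein (a tested
invariant). N-terminal methionine is never removed. Sliding windows
(immunopeptidomics) enumerate every substring of each requested length.
Variants apply one substitution at a time — no combinatorial stacking —
with the stated reference residue checked against the sequence and
mismatches skipped loudly. Precursors are the peptide × charge cross
product, deduplicated on (sequence, charge, modification set), keeping the
first occurrence (deterministic and order-preserving, rather than
keep-highest-intensity).

## Prediction

The predictor contract is two functions returning spectra and iRT values
aligned 1:1 with the input ions. The remote client speaks the
triton-style JSON of Koina-like services (`peptide_sequences`,
`precursor_charges`, `collision_energies` in; `mz` / `intensities` out),
batched at 1000 ions, with negative placeholder intensities dropped;
network failures surface as typed errors after bounded retries. Tests
drive it through a synthetic recorded-response stub, so nothing in the
repository needs a network.

The offline fallback predictor is deliberately crude: singly charged b/y
ladders with intensity y_i = i/(n−1) and b_i half that, base peak scaled
to 1.0; iRT is the Kyte–Doolittle hydropathy sum of the sequence. The ramp
makes every fragment's weight an explicit linear function of its ordinal,
which is exactly what makes the planted-twin studies analytically
tractable (below). It is a pure function — bit-identical on repeat — and
it is not a fragmentation model: absolute scores from it must never be
compared with Prosit-scale thresholds. The additive iRT has one important
property shared with real retention behaviour: sequence permutations
co-elute exactly.

Spectrum post-processing offers top-n selection (ties broken toward lower
m/z) and a relative-intensity floor (keep I ≥ fraction × base peak); both
are idempotent and neither is applied by default.

## Grouping

Candidate pairs satisfy |Δm/z| ≤ tol and |ΔiRT| ≤ tol_iRT, both boundaries
inclusive (matching the ± phrasing of such tolerances). A ppm tolerance is
evaluated against the smaller m/z of the pair — symmetric and
conservative; the reference choice is a convention, so it is stated and
tested rather than assumed. Defaults are 10 ppm MS1 and ±5 iRT. The
implementation sorts by m/z and slides a window (n·log n + output), and is
equivalence-tested against the all-pairs definition on hundreds of random
instances. Entries lacking an iRT can never satisfy the iRT condition;
pairs touching them are rejected and counted, never silently passed. No
conversion between empirical minutes and dimensionless iRT is attempted —
libraries carrying RTINSECONDS are flagged as `minutes` and refuse to mix
with predicted iRT.

## Peak matching and similarity

Matching is greedy closest-first within the additive tolerance
`Δ_allowed = tol_Da + ppm·10⁻⁶·min(m/z)` (two knobs, superset behaviour
when both are set; defaults 0 Da + 10 ppm). Ties on |Δm/z| prefer the
lower index in the first spectrum, then the second, making the match
fully deterministic. The implementation processes candidates in ascending
(|Δ|, i, j) order, which is provably the same as repeatedly extracting the
closest remaining candidate.

NDP and NSA use outer-join semantics: unmatched peaks enter with intensity
0 on the absent side, and a zero-intensity partner carries zero weight no
matter the exponent. The weighted cosine is
C = Σ W_a W_b / √(Σ W_a² Σ W_b²) with W = I^m (m/z)^n; NDP = C², and
NSA = 1 − 2·arccos(C)/π computed from the *unsquared* cosine — the
spectral-angle convention of the intensity-prediction literature that the
0.7 threshold comes from (the squared variant is one flag away; this
package pins the unsquared convention and oracle-tests it). The greedy
cosine instead uses only matched pairs in the numerator with raw
intensities, over full-spectrum norms — the matchms convention, which is
cross-checked against matchms itself on instances where the two greedy
orders provably coincide. All scores are clamped to [0, 1]; empty spectra
score 0; identical spectra score exactly 1 (Cauchy–Schwarz equality).

Exact duplicate m/z values within one peak list are merged by summing
intensities at construction, so peak lists are strictly increasing in m/z.

## Pipeline semantics

"Above the threshold" is implemented inclusively (score ≥ t). Peptide
groups are connected components of the indistinguishable-pair graph
(computed with networkx), not cliques — the analogy to protein groups and
the existence of >2-member groups both point to components. Groups are
reported sorted by size then lexicographically; the summary reports the
involved-precursor fraction with its numerator and denominator explicit.
A configurable per-precursor pair cap guards against quadratic blow-up in
dense m/z regions, off by default and loud when it trims. Outputs
(pair table, summary, manifest with config + input checksum) are
byte-reproducible; partial outputs are deleted on failure. Mirror plots
normalize each side to base peak = 100% (raw mode behind a flag) and pin
the SVG hash salt so renders are byte-identical.

## Synthetic twin studies

The generator plants ground truth into random uniform-composition
proteins (realistic amino-acid frequencies are a non-goal): for a chosen
fraction of eligible tryptic peptides it creates a mass-preserving twin —
adjacent swap of two internal non-K/R/P residues, I↔L exchange, or the
isobaric A+N↔G+Q double substitution at positions ≤ 3 apart — and splices
it into a fresh carrier protein between tryptic anchors (prefix ending R,
suffix starting A), so strict tryptic digestion re-emits it exactly.
Swaps avoid the termini because moving the C-terminal K/R would change the
carrier's digestion. Deamidation-style decoys (N→D / Q→E, Δm ≈ +0.984 Da)
are planted the same way to test rejection: they are digestion-neutral but
sit far outside any ppm-scale MS1 tolerance. The registry lists every
planted pair with its operation and mass delta; everything is reproducible
from the seed.

Default study conditions: 200 proteins of 200–400 residues, 5% twin
fraction, 2% decoy fraction, strict trypsin, lengths 8–20, charges +2/+3,
10 ppm MS1, ±5 iRT, 10 ppm MS2, NSA.

**Study threshold.** Under the fallback ramp the NSA cost of an edit is a
closed form. For the default √-intensity weights, w² of a fragment is its
intensity, and the total intensity mass of an n-mer is
S = 1.5·Σk/(n−1) = 0.75·n. A planted edit pair at 0-based positions
(i, j) changes b_{i+1}…b_j and y_{n−j}…y_{n−i−1}; the worst feasible case
is the isobaric substitution at (0, 3) on an 8-mer, which changes b₁–b₃
and y₅–y₇ — exactly half of S — giving cosine ½ and **NSA = 1/3 exactly**
(observed minima in the studies hit 0.3333…). The study threshold is
therefore 0.30: just below the analytic minimum of the planted family, far
above the near-zero scores of unrelated co-grouped peptides. This number
is a property of the fallback ramp, not of real spectra; with a trained
intensity model the conventional 0.7 applies.

**What the studies show — and don't.** Passing them demonstrates that the
machinery is correct: every mass-preserving twin lands in the candidate
set, every Δm > tolerance decoy stays out, scores match independent
oracles, and the involved-precursor fraction equals the planted fraction
up to registered accidental collisions. They say nothing about the
*prevalence* of twins in real proteomes, which depends on real sequence
composition and real intensity models; reproducing published full-proteome
counts would require downloading hundreds of reference proteomes and a
hosted prediction service, both outside this package's test envelope.

## Problem sizes

The shipped studies are sized for a single CPU: 200-protein proteomes
(≈5,000 precursors), 1,000-instance oracle sweeps with ≤30-peak spectra,
and 100-library format round-trips. All sizes are constants at the top of
the relevant tests and scale linearly if larger runs are wanted.
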