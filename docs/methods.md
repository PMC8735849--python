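# Methods

This note documents the models, rules and numerical choices behind
`nudipep`, and what the synthetic benchmark does and does not show.

## Translated homology search

Queries are mature prohormone proteins; subjects are transcript contigs.
Each contig is translated in six frames under the standard genetic code
(stops as `*`, codons containing `N` as `X`, trailing partial codons
dropped; frame numbering follows the BLAST convention, −1…−3 reading the
reverse complement). Every query × frame pair is aligned with an exhaustive
Smith–Waterman local alignment — no heuristic seeding, because inputs are a
few dozen queries against a few hundred contigs, not a genome. Scoring is
BLOSUM62 with affine gaps (open 11, extend 1, the classic TBLASTN defaults),
overridable via `ScoringConfig`. `X` is made score-neutral (0 against every
residue) since it stands for untranslatable codons. Alignment is delegated
to Biopython's `PairwiseAligner`; the test suite checks it against an
independently written affine-gap dynamic program on hundreds of random short
pairs. Ties among co-optimal alignments resolve to the smallest query start,
then smallest subject start, so reports are deterministic.

An expectation value E = K·m·n·exp(−λS) with the gapped BLOSUM62 parameters
(λ = 0.267, K = 0.041) is attached for ranking only; it is not comparable to
values from a heuristic search over a different database and no conclusions
rest on it. Published percent-identity/E-value tables for real assemblies
depend on the exact reads, assemblers and search heuristics and are
explicitly out of scope; the homology stage is instead validated by
planted-ORF recovery (100 % identity in all six frames, substitution-rate
experiments checked against the generator's manifest).

The candidate precursor is the longest stop-free segment of the hit's frame
translation that overlaps the aligned region, extended to the flanking stop
codons or contig ends; a leading Met is not required because transcripts may
be 5′-truncated. A candidate is "complete" when its length reaches the
configurable threshold (default 0.95, boundary inclusive) times the query
length.

## Signal peptide stand-in

Dedicated predictors are deliberately not reimplemented; external calls can
be injected per prohormone id and take precedence. The built-in heuristic
captures the two features those tools rely on most: a hydrophobic core — the
first run of ≥ 8 consecutive residues from {A, I, L, M, F, W, V, C} within
the first 30 positions — and a von Heijne-style (−3,−1) cleavage context:
the signal ends at the first position within 10 residues after the core
whose residue is small (A or G) with a compatible −3 residue
(A, G, S, C, T); failing that, at the core's end. Absence of a core means no
signal, and the precursor is processed from position 1 (several real
prohormones are annotated without signal sequences). The heuristic is a
coarse stand-in: it has no learned weights, and real signal peptides with
unusual cores or cleavage contexts will be missed or mis-placed — which is
why the injection table exists.

## Cleavage model

Prohormone convertase specificity is approximated by deterministic rules
rather than a trained model whose coefficients are unavailable:

- **Dibasic**: every maximal run of K/R containing an adjacent pair from the
  motif set (default KR, RR, KK, RK) is cut once, after the run's last
  residue. The rightmost rule means overlapping motifs (KKR) never produce
  zero-length peptides.
- **Monobasic**: an isolated residue from the monobasic set (default {R})
  cleaves only when no other basic residue lies within ± 3 positions
  (configurable spacing). This is a documented guess at the minority rule;
  real monobasic processing is context-dependent, so the site-injection
  table accepts external calls verbatim.
- No cuts inside the signal region; positions are 1-based, cleavage after
  the position.

Between-cut segments are stripped of up to two basic residues at each end.
A stripped core ending in Gly before a cut (or the sequence end) yields the
amidated peptide — the Gly is the amide donor and is removed — and,
optionally, the Gly-retaining free acid (off by default; whether such
variants belong in a search library is an open judgement call, and leaving
them out keeps libraries minimal). N-terminal Gln/Glu cores yield both the
unmodified and pyroglutamated forms, since both are routinely observed.
Acetylation is emitted only when enabled (it appears on specific peptides,
not globally; emitting it everywhere doubles the library for no benefit).
Cores shorter than 2 residues are dropped; a segment yielding more than 8
variants is capped with a warning. Conservation is an enforced invariant:
leading basics + core (+ donor Gly) + trailing basics over all segments
reconstruct the post-signal precursor exactly.

## Masses and matching

Residue masses are the standard monoisotopic values fixed at 5 decimals
(G 57.02146 … W 186.07931), water 18.01056 Da, proton 1.00728 Da; PTM deltas
are amidation −0.98402, pyroglutamation −17.02655 (Gln) / −18.01056 (Glu),
acetylation +42.01057. [M+H]⁺ is additive over these constants; arithmetic
is double precision and rounding happens only in reports (masses to 3–6
decimals, ppm to 1). The residue table is cross-checked against an
independent mass-spectrometry library in the tests.

Matching assumes singly protonated, singly charged ions (MALDI reflectron);
adducts and multiple charging are out of scope. The library is sorted by
mass and queried by bisection (the window [mz/(1+t·10⁻⁶), mz/(1−t·10⁻⁶)]
for tolerance t ppm); an all-pairs brute-force matcher serves as the test
oracle. The signed convention ppm = (obs − theo)/theo × 10⁶ reproduces the
signs of the published error column. Default policy reports **all** library
entries within tolerance, flagging multi-candidate peaks as ambiguous;
`best-only` takes the minimum |ppm|, ties broken by lower mass then
lexicographic sequence. Leu/Ile are distinct letters with identical mass;
both are reported when both are in the library, and motif scanning treats L
and I as equivalent by default for the same reason.

Recomputation of the published theoretical masses agrees to printing
precision (±0.002 Da for the short modified peptides, ±0.003 Da for a few
long unmodified ones, consistent with rounding in the original tool) with
one exception: the two SGYLAFPRMamide rows print a value 1.000 Da above the
additive result. The computed value (1040.535) is reported and the printed
one retained for comparison as a documented expected-fail; the fixture peak
matching therefore uses the printed masses, which is the library the
published matching was performed against.

## Family profiles

A neuron's profile counts **distinct peptides** — (core sequence,
modification set) pairs — per prohormone family, never peaks, so the
acetylated and unacetylated forms of one core count twice and a peak
matching two isobaric variants counts each once. Family labels attach at
library construction from the query prohormone and propagate through
assignments; a peptide assigned under two families triggers a warning
rather than silent double counting. The presence matrix is boolean
(count ≥ 1) over the union of families, invariant to profile order, with
shared/unique summaries (families in all neurons, per subset, unique to
one).

## Synthetic data

The generator emulates what the analysis assumes about real data:
precursors are signal + cassettes `spacer·KR·core(+G)·KR` with cores drawn
from non-basic residues (lengths 5–10, ~half carrying an amidation donor
Gly), so rule-based cleavage recovers exactly the planted peptides;
transcripts are uniform-synonymous-codon reverse translations inside random
UTRs with a stop codon closing the reading frame on both sides, flipped to
the reverse strand half the time; spectra have one peak per surviving
peptide at mh·(1 + ε·10⁻⁶), ε ~ N(0, σ), dropout per peptide, and uniform
contaminants on 530–5000 Da re-drawn out of the ppm neighborhood of every
library mass. Planted masses are kept ≥ 1 Da apart so no realistic noise
excursion can cross-match at the default tolerance. An adversarial mode
instead plants decoys at a fixed ppm offset (e.g. 150 ppm) inside the
window, to exercise ambiguity flagging. One seed fans out to named
per-component streams, so adding a stream never perturbs existing draws and
all outputs are bit-reproducible.

Default conditions — 3 prohormones, 2–5 peptides each, signal 18–30
residues, UTRs 30–120 nt, σ = 20 ppm (comfortably inside the ≤ ~160 ppm
errors seen in the real spectra), 5 contaminants, dropout 0.2,
substitution 0 — are the conditions of the end-to-end recovery benchmark:
annotate → predict → match → profile reproduces the manifest's family
presence exactly over 20 seeds, and precision/recall are 1.0 in 100 seeded
noisy runs. What this does **not** show: real spectra have isotope
envelopes, adducts, intensity structure and correlated calibration drift;
real precursors have non-canonical cleavage and PTMs beyond the registry;
real assemblies have indels and chimeras. Passing the benchmark demonstrates
the pipeline's bookkeeping and matching logic, not instrument-level
performance.

## Problem sizes and other numerical choices

Tests run at desk scale by design: alignment-oracle checks use 200 random
pairs of length ≤ 8 (where exhaustive dynamic programming is unambiguous),
matcher-oracle checks 200 random libraries of ≤ 15 entries, end-to-end
recovery 20 seeds of the default dataset (~7–15 true peptides each). The
whole suite completes in a few seconds. The completeness boundary uses a
1e-9 epsilon so 95/100 passes the 0.95 threshold despite float
representation. Peak lists are sorted on ingestion, retain but flag peaks
outside the surveyed 530–5000 m/z range and duplicate masses, and reject
non-positive masses outright. Lowercase sequence input is uppercased
silently; any other normalization (e.g. U→T) is rejected rather than
guessed.

## Known limitations

- The cleavage and signal heuristics are transparent stand-ins, not trained
  predictors; both accept external calls to close the gap.
- E-values are approximate and only ordinal.
- No isotope, intensity or FDR modeling; the simulator's contaminants are a
  structural stand-in for chemical noise, not a statistical model of it.
- mzML/raw-spectrum handling is out of scope; inputs are centroided
  [M+H]⁺ lists.
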