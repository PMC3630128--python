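# Methods

This note documents the models and procedures implemented in `subspec`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## 1. Profile HMM architecture and scoring

Each substrate (sub)group is represented by a plain match/insert/delete
profile over the 20 standard amino acids:

* **Match-state assignment.** An alignment column becomes a match state
  when its gap fraction is below 0.5; exactly 0.5 counts as match.  A
  zero-match alignment is an error.
* **Emissions.** Match emissions are per-column residue counts plus
  `pseudocount_weight × background`, normalized.  The default
  `pseudocount_weight = 1.0` (Laplace-like) is deliberate: substrate
  groups go down to two sequences, and unsmoothed models would assign
  −∞ to residues common in the family but absent from the tiny training
  set.  Insert states emit the background distribution, so insertions
  are scored by their transition costs only.
* **Transitions.** Each training row induces a unique path through the
  skeleton (residue in a match column → M, gap there → D, residue in an
  insert column → I).  Counts are smoothed with the same Laplace weight
  and normalized per state.  The moves I→D and D→I are fixed to
  probability zero, as is common profile practice; the rare training
  transitions of those two kinds are dropped from the counts (the
  architecture cannot represent them), which is documented behaviour,
  not an accident.
* **Null model and bit score.** The background defaults to uniform 1/20
  and is overridable with training-set frequencies.  The score of a
  query is the base-2 log-odds of the best global state path: emissions
  contribute `log2(p/background)`, transitions `log2(p)`, and the null
  model carries no length penalty.  Consequently a single-match model
  that emits `A` with probability 1 scores `log2 20 ≈ 4.32` bits on the
  sequence `A` — a convenient closed form used in the tests.  The
  ambiguity code `X` scores zero log-odds in any emitting state, so an
  all-`X` query lands at (or near) zero bits and below any positive
  threshold.
* **Global alignment mode.** Domain sequences are pre-excised by
  contract, so no local entry/exit states are modeled.  Scoring is the
  standard O(M·L) Viterbi dynamic program; its correctness surface is
  an exhaustive enumeration oracle over all legal state paths for small
  models (≤ 4 match states, length ≤ 6), with exact agreement required
  to 1e-9 bits.

E-values are not computed: there is no calibration data for this model
family, and reliability is defined on bits alone.

Because this is a from-scratch implementation, bit scores are not
numerically identical to those of any external HMM engine; the
reference thresholds of 325 bits (AT libraries) and 625 bits (A
libraries) therefore transfer only approximately and are configurable
per library.  Synthetic libraries calibrate their own threshold as the
midpoint between the mean in-group and mean out-group training scores.

## 2. Libraries, thresholds and prediction

A *single* library has one model per substrate with ≥ 2 member
sequences; singleton substrates are excluded and reported (no reliable
model can be estimated from one observation — their sequences should
ideally score below threshold, and the validation bookkeeping counts
that as favourable).  An *ensemble* library replaces the single model of
every substrate with ≥ `size_threshold` members (10 for AT, 15 for A)
by one model per part of a supplied clade partition (2–4 parts); all
other substrates keep their single model.

`classify` takes the best-scoring model over the whole library (stable
tie-break by model name), predicts its substrate, and flags the
prediction unreliable when the score is below the library threshold.
Raising the threshold can only flip the flag, never the winner.
Substrate synonyms that denote interchangeable specificities
(dhb/sal, thr/allo-thr, hpg/hpg2Cl, dhab/dht, dhpg/dpg, pro/me-pro,
abu/iva, masp/me-asp) are scored as one label during validation, and an
ambiguous truth label (`"a|b"`) is correct when the prediction matches
any alternative.

## 3. Alignment preparation

* **Terminal trimming.** Alignments are homogenised by iterating
  align → measure terminal overhang → cut.  The overhang is the run of
  leading (trailing) columns that still contain a gap; residues falling
  in those columns are removed row-wise, so rows without extensions
  lose nothing, and the loop ends when the first and last columns are
  gap-free.  `max_rounds` defaults to 10; exhausting it yields a
  warning on the result rather than an exception.  The aligner is a
  pluggable contract (same ids in, residues unchanged); an external
  MAFFT wrapper is provided for real data and a deterministic
  template-guided realigner for tests and synthetic data, so the loop
  is testable without any external binary.
* **Deduplication.** Near-duplicates are removed greedily in input
  order: a sequence is dropped when its global pairwise identity to an
  already-kept sequence *of the same substrate* reaches the threshold
  (default 0.98).  Identity is matches divided by aligned columns of a
  global pairwise alignment (match 1, mismatch 0, affine gap cost);
  double-gap columns cannot occur pairwise, so the denominator is
  unambiguous.  Cross-substrate removal is disabled on purpose —
  identical sequences with different annotated substrates are signal,
  not redundancy.  No numeric criterion is canonical here; 0.98 removes
  trivial resubmissions without collapsing paralogs and is a CLI knob.

## 4. Conservation analysis

Columns are numbered by a reference row (the k-th non-gap column of the
reference is residue k), mirroring the convention of numbering AT
positions by the E. coli FabD structure and A positions by GrsA.  A
column is conserved for a group only under the strictest reading of
100% identity: every member carries the same residue and none has a gap.
Selections are: columns conserved in ≥ k groups, optionally excluding
the *globally* conserved columns.  "Global" requires conservation in
every group **with the same consensus residue**; the looser reading
(conserved everywhere, possibly with different residues) would delete
exactly the discriminative columns the selection exists to keep, so it
is rejected.  Reduced alignments are plain column slices, so extraction
commutes with row subsetting.

## 5. Trees and clade partitions

Distances are simple p-distances (mismatches over columns where both
rows have residues; pairs with no comparable column get distance 1 with
a warning).  No distance correction is applied — the choice keeps the
module assumption-free, and the NJ implementation is the classic
Saitou–Nei algorithm with the Q criterion, branch lengths
`d/2 ± (r_i − r_j)/(2(n−2))`, negative lengths clamped to zero with the
deficit moved to the sister branch, and deterministic lexicographic
tie-breaking (a cluster is labelled by its smallest leaf id).  On
additive matrices the output reproduces the generating tree's path
distances to 1e-9 and the generating topology exactly; it also attains
the exhaustive minimum-evolution optimum for n ≤ 6.  These properties
are the module's acceptance surface.

Clade partitions for ensembles were historically drawn by eye from NJ
trees; the reproducible stand-in here is: midpoint-root the tree, take
the maximal clades consisting purely of group members as initial parts,
then repeatedly merge the smallest part into its topologically nearest
part until at most `max_parts` (≤ 4) parts remain and each has at least
`min_part_size` members.  Groups smaller than `2 × min_part_size` are
returned whole with a `not_subdivided` flag.  A partition can instead be
loaded from a parts table when the authoritative grouping exists
elsewhere.

## 6. Validation

Every labeled sequence is counted exactly once as correct (reliable and
matching), false (reliable and wrong) or below-threshold.  A right
answer below threshold counts as below-threshold, matching the
three-way bookkeeping of the reference tables.  Coverage is
`100·(1 − below/n)` and correct-of-covered is
`100·correct/(correct + false)`; all percentages are recomputed from the
integer counts on access, so the report can never disagree with itself.

Leave-one-out cross-validation rebuilds, for each held-out sequence,
only the model(s) trained on its own (sub)group — sibling ensemble
parts are untouched — and classifies the held-out sequence against the
full rebuilt library.  When removal empties a one-member subgroup that
model is dropped for the fold and the event logged; size-2 groups
degrade to single-member models and are flagged.  Re-inserting the
held-out sequence reproduces the resubstitution prediction bit-for-bit
(tested), and on every synthetic fixture examined LOO accuracy does not
exceed resubstitution accuracy.

## 7. The synthetic generator

The generator produces what the classifier's claims are about:
families with a drifting scaffold, a small planted specificity code and
convergent labels.

* A random ancestor evolves along a clade-structured binary tree.
  Within-clade topologies are random (uniform pair joining); clade
  roots hang off a caterpillar backbone whose links are chains of
  `backbone_edges` unit edges.  Every unit edge substitutes each site
  independently with probability `scaffold_mutation_rate` (default
  0.03), uniformly over the 19 alternatives — controllable divergence,
  not biochemical realism (no rate heterogeneity, no substitution
  matrix, no indels).
* Each label owns a disjoint set of `specificity_positions` scaffold
  columns; every leaf's positions are overwritten with its label's
  signature residues, so the true label is always recoverable from
  those columns and mutating non-planted positions can never change it.
* A convergent label contributes two clades: the major clade sits on
  the backbone like any other; the minor clade attaches as a near
  sister (1 unit edge) of the **last other label's** clade.  The minor
  members therefore share far more scaffold with that neighbour than
  with their own substrate's majority — the analog-among-homologs
  situation.
* Everything is driven by one integer-seeded PCG64 generator in a fixed
  traversal order, so datasets are byte-identical across runs and
  platforms.

**Convergent benchmark** (`convergent_benchmark`): group sizes
(18, 10, 10) with S1 split 15 + 3, scaffold 120, 3 signature columns
per label, rate 0.03, backbone links of 12 edges.  The sizes follow the
regime of real substrate groups (a handful to a few dozen members, the
convergent group above the A-domain ensemble threshold of 15).  The
parameters realize the designed failure mode by a bit-score argument:
the single S1 model gives a minority-clade residue only about
`log2(20·3/18) ≈ 1.7` bits where the major clade disagrees, while the
neighbouring S3 model — one short attachment away — gives the same
residue ≈ 4 bits; with ≈ 45% of the 120 columns divergent between the
two S1 clades this deficit (~2.4 bits × ~50 columns) overwhelms the
3-column signature bonus (~8 bits × 3), so the minority members flip to
S3 under the single library, and only there.  The clade-specific
ensemble model removes the dilution and the signature decides.

**Divergence contrast** (`divergence_contrast_benchmark`): two groups of
8 (one at the base rate, one at 6× the rate) and a background group of
6.  Held-out members of the divergent group lose their private residues
from the refit model and drop below the calibrated threshold or flip,
while the cohesive group is insensitive to any single removal — the
ordering that leave-one-out validation is expected to expose.

What passing these benchmarks does **not** show: performance on real
domains.  Real A/AT families have indels, biased residue composition,
correlated sites and unevenly sampled clades; the planted signature is
cleaner than any real specificity code.  The benchmarks demonstrate the
mechanisms (dilution vs. clade-specific models; divergence vs. LOO
stability), not field accuracy, which requires the curated reference
alignments (see `tests/test_acceptance.py` for the expected local data
layout).

## 8. Numerical and formatting choices

* Probabilities are serialized with `repr`, so model libraries
  round-trip losslessly; the library format carries a version line and
  read rejects a mismatch.
* Emission/transition rows must sum to 1 within 1e-9 (validated on
  construction).
* Log-odds use −∞ for zero probabilities; smoothed models never produce
  −∞ scores (tested).
* FASTA is wrapped by the underlying writer; substrate codes are
  case-insensitive on input and canonicalized on output; residues B, Z
  and U are rejected while X is accepted and scored neutrally.
* Problem sizes in the default test run and the acceptance script
  (38-sequence convergent benchmark, 22-sequence LOO contrast, 200
  Viterbi oracle trials, 100 additive NJ matrices) are chosen so the
  whole suite completes in about a minute on one CPU while exercising
  every code path; the effects they measure are large at these sizes
  (≈ 8 percentage points single-vs-ensemble, ≥ 25 points LOO contrast).

## 9. Known limitations

* Bit-score thresholds from the reference setting (325/625) are not
  portable to other scoring engines or to synthetic data; recalibrate
  per library.
* The clade-partition procedure is a reproducible proxy for manual
  clade reading; with very unbalanced trees the greedy merge can join
  parts a human would keep separate.  Supplying an explicit parts table
  bypasses it.
* Whether reference models are best trained on full-length or
  reduced-column alignments is left to the caller (both are supported by
  passing the corresponding alignment); no attempt is made to decide
  this ambiguity.
* The external-aligner wrapper shells out to MAFFT and is exercised only
  when the binary is present; tests use the template realigner.
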