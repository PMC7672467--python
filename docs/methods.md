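# Methods

## Scope and model

`offscan` addresses genome-wide off-target prediction for the SpCas9 knockout
system: given a guide RNA (a 20-nt protospacer followed by a 3-nt PAM,
canonically NGG), find every genomic locus the nuclease might cleave despite
sequence mismatches, score each locus with several hypothesis-driven
specificity models, and integrate those scores (plus externally computed tool
scores) into a single cleavage probability with a boosted-stump ensemble.

The candidate model is deliberately restrictive, matching the dominant
experimental evidence for SpCas9: a candidate is exactly 23 nt (20-nt
protospacer-equivalent + 3-nt PAM), the PAM must match an IUPAC pattern
(default NGG; NRG supported), and at most 6 mismatches are allowed within the
20-nt region. DNA/RNA bulges (insertions or deletions at the RNA–DNA
interface) are out of scope: sites spanning more or fewer than 23 nt are
excluded by construction in the search and rejected by rule in curation.

Position convention, used identically by every component: position 1 is the
PAM-distal (5') end of the protospacer, position 20 abuts the PAM, the PAM
occupies 21–23. Coordinates are 0-based half-open on the forward reference
strand (BED convention — the underlying data sources do not fix one, so the
package declares its own); a minus-strand candidate stores the reverse
complement of the reference window so `site_seq` always reads
protospacer-then-PAM 5'→3' on the matching strand.

## Search

`enumerate_candidates` scans every 23-nt window of every contig on both
strands (the minus strand via the reverse-complemented contig with offsets
mapped back to forward coordinates). The implementation vectorizes the window
comparisons with numpy (byte-level equality against the protospacer, IUPAC
lookup tables for the PAM), but its correctness contract is defined entirely
by a naive both-strand sliding-window scan, which the test suite implements
independently and compares against on randomized genomes, guides, mismatch
budgets and PAM patterns.

Degenerate-input policy: windows containing any base outside {A,C,G,T}
(N or other ambiguity codes) are skipped whole — no fractional matching —
and chromosome-end windows shorter than 23 nt are dropped. Opposite-strand
hits over the same span are distinct candidates (they have different site
sequences).

## Curation and labeling

Validated off-target records from heterogeneous detection assays are reduced
to the candidate population above by four rules applied in a fixed order,
each record charged to its first failing rule so the filter log is exactly
conservative (kept + per-rule rejections + orphans = input):

1. **length** — site sequence must span 23 nt;
2. **pam** — last 3 nt must match canonical NGG (NAG/NGA and other
   non-canonical PAMs are rejected);
3. **mismatch** — at most 6 mismatches against the guide;
4. **guide GC** — records of guides whose protospacer GC content exceeds 75%
   (strict) are dropped; GC is computed on the 20-nt protospacer only.
   GC-rich guides are promiscuous cutters and would dominate the positive
   class.

Records naming an unknown guide are counted as orphans, never silently
dropped. Within one (guide, cell type) group, records at the same locus from
different assays merge into one record carrying the sorted union of assay
names. Labeling marks a candidate 1 iff a validated record with the same
(chrom, start, end, strand) exists for the same guide; a validated record
that matches no candidate is returned in a reconciliation log, because it
indicates the search and the curation disagree (different build or
convention). Locus identity is exact coordinate equality; a ±k-bp tolerance
flag exists (default 0) because whether near-identical loci offset by 1 bp
should merge is genuinely unsettled for mixed-assay data.

Cell types matter because cleavage specificity is heterogeneous across them;
the split, CV and reporting machinery all stratify by cell type. Cross-build
coordinate conversion is out of scope: the CLI carries a declared build label
as metadata only.

## Native scores

All four scores depend only on (guide, site sequence, tables), never on the
genomic position, and share the position convention above. All are oriented
"larger = more cleavage-prone".

* **CFD-style** — product over mismatched positions of a per-(position,
  guide base, site base) activity factor, times a factor for the 2-nt PAM
  tail; 1 at a perfect NGG match.
* **MIT/Hsu** — `prod(1 − W[p]) × 1/(((19 − d̄)/19)·4 + 1) × 1/n²` with `n`
  the mismatch count and `d̄` the mean gap between consecutive mismatch
  positions; 1 at a perfect match. For `n = 1` the pairwise-distance term is
  undefined; its factor is taken as 1 (the convention of the original
  webtool family). `n = 0` returns 1 before any factor is evaluated.
* **CCTop** — the published quantity is a penalty `Σ 1.2^p` over mismatched
  positions; the package exposes the negated value so a perfect match scores
  0, the maximum. This keeps every feature column monotone in the same
  direction, which simplifies both evaluation and stump semantics.
* **CROP-IT-style** — the protospacer is partitioned into contiguous
  segments with uniform within-segment weights; the score is the weight mass
  of *matched* positions divided by total mass, so perfect match → 1 and
  all-mismatch → 0.

Numeric constants live in versioned JSON config files validated for
completeness at load (all 240 CFD keys, 16 PAM tails, 20 MIT weights, exact
segment coverage of 1..20); a missing key is a load-time configuration
error, never a silent zero at scoring time. The MIT weight vector is the
widely reproduced constant of the original method. The shipped CFD factor
table and CROP-IT segment weights are **synthetic representative defaults**
(marked in filename and provenance string): they reproduce the structural
properties the methods are defined by — factors in (0,1], canonical PAM
factor 1, stronger penalties toward the PAM-proximal seed, transitions
tolerated more than transversions — but they are not transcriptions of the
original experimentally derived tables. Users needing numerical agreement
with the original webtools should supply transcribed tables through
`ScoreTables.from_files`; every structural test and the ensemble machinery
are insensitive to this substitution.

Energy-based and learning-based tools are ingested as external score columns
keyed by (guide, chrom, start, end, strand); their models are not
re-implemented. Missing external values are imputed with the column minimum
(the most benign assumption, since all columns are cleavage-prone-upward)
and flagged with a companion `<name>_missing` indicator column; duplicate
locus keys in an external table are an error.

## Evaluation

ROC and PR curves are computed from first principles with tie-grouped
thresholds (one operating point per distinct score). ROC-AUC uses the
trapezoid rule and equals the normalized Mann–Whitney U with ties counted ½
(asserted against a brute-force pair-counting oracle). PR-AUC uses the
average-precision step sum, not trapezoidal interpolation, because
trapezoids overestimate area in PR space; this is recorded as a
comparability caveat when relating numbers to reports that interpolate.
Metrics are emitted both pooled and per cell type, since which of the two a
published figure used is often unstated. Single-class slices yield an
explicit undefined-metric error (NaN plus a note in batch reports), never a
fabricated value.

## Ensemble

The integrated score is the class-1 probability of a SAMME.R (real-boosting)
AdaBoost ensemble of depth-1 decision stumps — hyperparameters frozen to the
reference protocol: 280 estimators, learning rate 0.1. Implementation
choices where the recurrence leaves freedom:

* stump search minimizes total weighted Gini impurity over all (feature,
  threshold) pairs, thresholds at midpoints between consecutive distinct
  sorted values; ties broken deterministically by lower feature index, then
  lower threshold;
* leaf class probabilities are instance-weight fractions clipped to
  [1e-15, 1 − 1e-15] before logs;
* the per-round weight update multiplies by
  `exp(−lr · (K−1)/K · y·log p(x))` with the true class coded +1 and the
  other −1/(K−1) (for K = 2: `exp(−lr/2 · (log p_true − log p_other))`),
  followed by renormalization, so instance weights remain a distribution
  after every round;
* a round degenerates — and training stops early, recording the actual round
  count — when no split improves impurity, when the chosen stump's weighted
  0/1 error exceeds ½, or when both leaves are pure (that last stump is
  kept: a separable problem needs one stump);
* with only constant features the model falls back to the class prior with a
  warning.

Class imbalance is handled by the boosting weights alone (no resampling).
Predictions are invariant to feature-column order because the model maps
columns by name. Models serialize to versioned JSON and reload
bit-identically. Training reports 5-fold stratified CV (per-fold class
counts within one of each other); CV is for reporting generalization, not
re-tuning — the frozen hyperparameters are used as-is unless the caller
changes them.

The correctness oracle for the recurrence is a second, loop-coded
implementation kept in the test suite, sharing no code with the vectorized
one; predicted probabilities agree to 1e-10 on small instances.

## Synthetic data

`make_genome` draws i.i.d. bases at a target GC (default 0.41, human-like).
`plant_sites` writes mismatched copies of the guide target (mismatch
positions drawn without replacement, mutated to a different base, reverse
complemented for minus-strand plants) into non-overlapping loci and returns
the exact truth table; each written window is re-read from the modified
genome and its profile recomputed as a post-hoc faithfulness guarantee.

`simulate_feature_table` draws a latent cleavage propensity z ~ N(0,1) per
candidate; tool column j is `signal_j·z + noise`, and within each cell type
the rows with the largest z are labeled 1 so the positive count is exactly
`round(prevalence × n)` (quantile thresholding — chosen over Bernoulli draws
so tests can assert exact counts; a `bernoulli` flag restores random
counts). Default shape mirrors the real benchmark's structure: seven tool
columns, three cell-type strata with sub-percent prevalences (0.54%, 1.02%,
0.06% — the real populations' rates), overall ≈0.4% positives.

What the simulation does *not* emulate: sequence-driven score structure
(columns are noisy monotone functions of one latent factor rather than of a
mismatch profile), inter-tool correlation structure beyond that single
factor, chromatin/epigenetic covariates, and assay-specific detection noise.
Passing tests therefore demonstrate that the machinery — search, labeling,
metrics, boosting — is correct and that ensembling over partially
informative columns helps under realistic imbalance; they do not certify
real-data accuracy of any specific tool column.

## Problem sizes

Test and acceptance runs use scaled-down instances chosen to keep every
quantity statistically meaningful: search-oracle equivalence on genomes of
1.5–15 kb (22 randomized instances), truth recovery on 25-kb genomes across
10 seeds, and ensemble evaluation on 60,000-row tables (≈250 positives,
≈50 in each 20% test split — enough positives that PR-AUC reflects ranking
quality rather than estimator noise, while a 280-round fit stays at a few
seconds). The real benchmark population this emulates is roughly 7× larger.

## Known limitations

* The shipped CFD/CROP-IT constants are representative, not transcriptions
  (see above); absolute score values differ from the original webtools even
  though every ordering property holds.
* Bulge-tolerant off-targets, non-SpCas9 PAM architectures, and cross-build
  coordinate conversion are out of scope.
* The PR-AUC convention (average precision) may differ from interpolated
  areas reported elsewhere.
* Exact-coordinate locus identity will under-merge assays that report
  cleavage positions with ±1-bp jitter unless the tolerance flag is used.
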