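# Methods

## Problem setting and model

The package classifies lysine-centered sequence windows as succinylated or
not.  The model assumes substrate specificity is carried by the *local
sequence composition* of the flanking region — residue frequencies, adjacent
dipeptide frequencies, and the frequencies of residue pairs at fixed
spacings — rather than by structural or evolutionary features.  A window is
the modified (or candidate) lysine plus `n = 15` residues on each side
(31 columns); this width follows the consistent finding across lysine-PTM
predictors that 31-mers perform best, and every composition statistic in the
package is defined over these fixed, pre-aligned columns.

Classification is a soft-margin SVM with RBF kernel
`K(x, x') = exp(-r ||x - x'||^2)` in the LIBSVM parameterization (cost `c`,
`gamma` = r; a Gaussian radius `s` maps as `r = 1/(2 s^2)`).  All features
are bounded compositions in [0, 1], so no additional scaling is applied
before the kernel.

## Window handling

* Coordinates in all files are 1-based (UniProt convention).
* Windows crossing a terminus are padded with `'-'`.  Pads are excluded
  from every numerator *and* denominator: an AAC/AAPC vector sums to 1 over
  the countable content, and the CKSAAP normalizer counts only slots whose
  two positions both hold standard residues.
* Nonstandard letters (B, J, O, U, Z) map to `'X'` on input and behave like
  pads, keeping the 20-letter feature space exact.
* Annotations on non-lysine residues are skipped with a warning rather than
  failing the run: public PTM tables contain isoform coordinate offsets, and
  a hard failure on the first offset row would make curated inputs
  unusable.

## Redundancy filtering

Fragment identity between two windows is the positionwise match fraction
over the 31 columns (pads and `'X'` never match; the denominator is the full
window length).  No realignment is performed — windows are already aligned
on the central K, which is how fixed-length fragments behave after
protein-level clustering.  `redundancy_filter` is a greedy first-kept scan
at a 40 % default threshold, optionally against a reference set for
cross-set (train vs. test) filtering, and is idempotent.  Protein-level
clustering of full sequences (conventionally CD-HIT at 40 % identity) is a
supported *preprocessing* step applied to the FASTA before it enters the
package; the package itself only de-redundifies fragments.

## Feature encodings

* **AAC** — 20-dim residue frequency vector, alphabetical attribute order.
* **AAPC** — 400-dim adjacent (overlapping) dipeptide frequency vector.
  Whether gapped pairs should also count is not a settled convention;
  adjacent-only is used here, with gapped pairs covered separately by
  CKSAAP.  For classification the AAPC block uses the screened subset:
  dipeptides with |probability difference| > 0.02 and P < 0.05 between
  classes, ranked by p-value.  The probability difference is computed on
  *pooled* counts (total occurrences over all windows of a class divided by
  the class's total pair count), and the test is a pooled two-proportion
  z-test on window-level presence counts.  If nothing passes the screen —
  possible on data without adjacent-pair structure — a hybrid's AAPC block
  is empty (the screened-subset construction applied literally), while a
  pure AAPC model falls back to the full 400 dimensions with a warning so
  it remains fittable.
* **CKSAAP** — for each ordered pair and spacing k = 1..5, the per-window
  feature is `count / (31 - k - 1)` (count divided by available slots,
  fewer when pads intrude), giving features bounded in [0, 1].  The
  dataset-level strength `C = log(P+/P-)` uses natural log; the ranking it
  induces is base-invariant.  When either class has a zero pair count, both
  classes receive a +1/+20 pseudocount (pair/marginal) before the ratio so
  C stays finite without disturbing the ordering of well-observed pairs;
  when both counts are positive the raw ratio is used, so the reported
  probabilities and C agree exactly.

## Informative pair selection

Mutual information is the plug-in estimator over the empirical joint
distribution, base 2.  CKSAAP counts are small integers, so MI is computed
on the raw count values with no binning rule.  mRMR ranks greedily: the
most relevant attribute first, then repeatedly the attribute maximizing
relevance minus mean MI with the already-selected set.  The ranking is
computed once on all 2000 attributes and truncated at the selection budget;
interleaving ranking with selection is a possible alternative reading of
the procedure, but rank-once-then-scan is the declared choice here.  The
"choose the attribute with lowest mRMR index score" phrasing in the original
five-step procedure is interpreted as *best mRMR rank* (rank 1 first), since
taking the literally worst-scoring attribute would contradict the criterion
being maximized.

Sequential forward selection walks the ranking in order, evaluating each
prefix by pooled stratified 10-fold CV MCC of the SVM.  The inner classifier
uses the fixed default configuration (`c = 1`, `gamma = "scale"`); only the
final model is grid-searched, since nested tuning of 2000-attribute scans is
not warranted at this scale.  The best-MCC prefix wins, ties go to the
smaller attribute count (parsimony), a perfect MCC stops the scan early, and
the budget (default 30) caps the set size.

## Model selection and evaluation

* Grid search: exhaustive over `c` in `2^-5 .. 2^15` and `gamma` in
  `2^-15 .. 2^3` (steps of `2^2`; 11 x 10 = 110 configurations), maximizing
  pooled CV MCC; ties prefer smaller `c`, then smaller `gamma`.
* Cross-validation: stratified, seeded, shuffled folds; fold sizes differ by
  at most one sample.  Metrics come from the confusion counts pooled over
  held-out folds.
* MCC with any zero denominator factor is defined as 0, keeping degenerate
  folds comparable during selection.  Sn/Sp/Acc with a zero denominator are
  0 by the same convention.
* ROC curves sweep the unique score thresholds (ties step simultaneously)
  and AUC is trapezoidal; it equals the tie-corrected Mann–Whitney U
  normalization, which the tests verify against an independent
  rank-statistic oracle.
* Probability scores are Platt-style: a sigmoid calibrator is fit on
  cross-validated decision values of the training set and applied to the
  margin classifier refit on all samples, so probabilities and decision
  values come from a single hyperplane.  The default call threshold is 0.5
  and is overridable at prediction time.
* No class weighting is applied despite class imbalance; MCC-driven
  selection already penalizes degenerate majority-class solutions, and the
  unweighted objective keeps the solver contract simple.  This choice is
  recorded for reproducibility.

## Synthetic succinylome generator

The generator emulates the two hallmark findings about succinylation
flanks: lysine enrichment well upstream/downstream of the site and
glutamate/aspartate depletion immediately around it, plus enriched k-spaced
residue pairs.  Defaults (the declared study conditions for all simulation
tests):

| parameter | default | meaning |
| --- | --- | --- |
| background | uniform over 20 residues | planted effects are the only structure; a natural-abundance mode exists |
| K log-odds | +0.7 at offsets −15…−1 and +6…+12 | ≈ twofold lysine enrichment in positive flanks |
| E/D log-odds | −1.2 at offsets −5…−3 and +5 | ≈ 0.3× acidic-residue depletion near the site |
| planted pairs | 10 attributes across k = 1…5, multiplier 8 | forced pair insertions, Poisson with mean (multiplier − 1) × background expectation |
| protein length | geometric around `mean_length`, floor 31 | every window fits |
| `effect_scale` | 1.0 | scales log-odds multiplicatively and interpolates multipliers; 0 disables the motif |

Site slots are laid out non-overlapping (centers a full window apart) so
planted flanks never overwrite one another; slot centers are forced to K and
randomly assigned positive/negative; positive flanks are redrawn from the
motif-adjusted per-offset distributions and then receive the pair
insertions (never touching the central K).  Output is byte-deterministic
given the seed.

What the generator does **not** emulate: natural residue abundances (by
default), protein homology and shared domains, adjacent-dipeptide
enrichment (the planted-pair channel starts at spacing k = 1, i.e. one
residue between the pair), position-dependent pair preferences, and any
mass-spectrometry acquisition bias.  Passing simulation tests therefore
demonstrates correct *recovery of planted structure*, not field performance
on real succinylome data.

## Problem sizes

The simulation suite and the acceptance script use a fixture of 500
positive / 1500 negative sites on 260 proteins of mean length 400 — large
enough that the planted effects dominate sampling noise while a full
feature-set comparison (including the 2000-dim CKSAAP model under 10-fold
CV) completes in a couple of minutes on one CPU.  Unit tests use smaller
corpora (tens to hundreds of windows) chosen per property.

## Known limitations

* The AAPC screening test and the two-sample logo use raw per-cell
  p-values (no multiple-testing correction) by default, mirroring the
  conventions of the tools this analysis style descends from; a Bonferroni
  flag exists for the logo table.  Expect ~5 % false cells under the null.
* On data where compositional signal is weaker than pair signal, hybrid
  models that include AAC need not dominate; the feature-set comparison is
  an empirical question per dataset, which is exactly why the CLI can sweep
  all seven feature sets.
* The per-window CKSAAP value normalizes by available slots; dataset-level
  strengths (Eq.-style conditional probabilities) are screening statistics
  only and never enter the per-window feature values.
* Real succinylome benchmarks depend on the curation snapshot and
  redundancy-filtering toolchain used to build them; numbers obtained on
  such datasets are not comparable across snapshots, and this package makes
  no attempt to ship one.
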