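# Methods

## Data model and ascertainment

A *site* is a single-nucleotide substitution keyed exactly on
(chromosome, 1-based position, ref, alt); two alt alleles at one position
are distinct mutations. Chromosome names are compared after stripping an
optional `chr` prefix. A dataset aligns, per site, the binary detection
status of each of K callers, the validation label (1 = confirmed somatic
by independent re-sequencing), optional genomic features, and optional
per-caller extras (quality score, filter flags).

Two structural invariants are enforced everywhere: **union
ascertainment** (every site was detected by at least one caller — sites
nobody called do not exist in the data, so the union contains all true
and all false positives by construction) and **validated labels only**
(sites whose validation failed are excluded at assembly). A validated
site detected by no caller is a fatal consistency error. VCF FILTER
columns are ignored on read by default, because a caller's emitted file
is taken to be its final call set; `--pass-only` restricts to
FILTER=PASS for callers that emit rejected candidates too.

## Combination statuses and the cumulative caller

The `2^K - 1` nonzero detection patterns partition the union. Per-subset
validation rates are kept at full precision and rounded to one decimal
only for display. The cumulative combined caller sorts subsets by
training validation rate, descending; ties are broken by larger subset
first (a larger subset estimates its rate more reliably), then label
lexicographically; empty subsets — possible when a test partition lacks
statuses seen in training — carry no rate and go last in label order.
Training rates closer than 0.5 percentage points (configurable) are
logged as near-ties, since sampling variation can then flip the learned
order between training and test data. Cumulative FP/TP rates divide by
the test partition's union totals and always end at (100, 100).

## The stacked model

With combination-status encoding, 4 numeric genomic features and 12
substitution types, the design matrix has 6 status indicators
(all-callers is the reference level) + 4 numeric columns + 11
substitution indicators (A>C, the first type in double-alphabetical
order, is the reference) + 6×15 = 90 status × feature products = 111
columns, plus an unpenalized intercept. The status encoding is the
default because it does not assume caller effects are additive; the
additive per-caller ("marginal") encoding is available as a
configuration option. Missing numeric features are imputed with the
training-set column median and flagged by a companion 0/1 indicator
column; prediction reuses the training medians and the training
indicator layout, so dropping sites (which would bias the ascertained
universe) is never needed.

### Penalized path solver

The ℓ1-penalized logistic objective (sum of per-site log losses plus
λ‖γ‖₁, intercept unpenalized) is minimized by proximal-Newton coordinate
descent: an IRLS quadratic approximation solved by cyclic coordinate
descent over a working set (currently nonzero coordinates plus KKT
violators), iterated until the KKT conditions hold — |score gradient| ≤ λ
for zero coordinates and gradient = −λ·sign(γ) for active ones — to a
per-sample tolerance (default 1e-7). All penalized columns, binary
indicators included, are standardized internally to zero mean and unit
variance before penalization, matching the default behavior of the
standard penalized-GLM software; coefficients are reported on the input
scale. The inner kernel is numba-compiled when numba is available, with
an equivalent pure-Python fallback.

The λ grid has 100 log-spaced values from λ_max (the smallest penalty
with an all-zero solution, computed from the null-model score) down to
λ_max·r, r = 1e-4 when n > L and 1e-2 otherwise, solved warm-started in
decreasing order. As is conventional for path software, the path stops
early once the fit saturates: when the deviance ratio exceeds 0.999 or a
step improves it by less than 1e-4 of itself. The tail it skips is the
near-separated regime whose coefficients diverge and which no
cross-validation curve ever selects; `devmax=1, fdev=0` forces the full
grid. Probabilities are clipped at 1e-9 in deviance computations and
IRLS weights floored at 1e-5.

### Cross-validation and selection

Ten stratified folds (drawn from the caller-supplied seed; a degenerate
single-class fold triggers a re-draw with a derived seed) estimate
per-λ held-out binomial deviance; deviance is the conventional loss for
penalized logistic paths. Folds whose own path saturates early carry
their last solution forward for the remaining grid points. The
one-standard-error rule picks the largest λ whose mean CV error is
within one standard error (across folds) of the minimum; the model is
then the whole-training-set path solution at that λ. Fixing the seed
fixes the folds, the curve and the fit exactly.

A known property of this estimator, confirmed against the reference R
implementation on identical data: at the 1-SE λ the surviving
coefficients carry a seed-dependent shrinkage bias of roughly 0.2–0.8
(standardized units) under strong sparse signal at n = 20,000 — the
deviance curve is flat near its minimum, so the 1-SE reach varies
widely — while at the CV-minimum λ the error stays below ~0.1. Tests
that check coefficient accuracy therefore distinguish the two operating
points explicitly.

### Saturated-model bridge

With the combo-only design and λ → 0, the model is saturated: each of
the 7 statuses gets its own fitted probability, which equals that
subset's empirical validation rate, so the stacked ranking reproduces
the cumulative ranker's ordering exactly. This bridge is tested to
1e-4 and is the reason the stacked model can only improve on the naive
ordering once genomic features enter.

## Single-caller refinement

For a caller exposing a quality score and per-filter pass/fail flags
over a broader candidate set, a logistic model on {quality, one
indicator per filter} is fit with the same path/CV/1-SE machinery.
Filters are opaque 0/1 flags — no attempt is made to reconstruct their
definitions. The candidate universe is the validated union universe, so
refined scores stay comparable with the other callers; sites outside
the candidate set rank below every scored site. Constant filter columns
are dropped with a warning; quality is used untransformed by default
(an optional rank transform exists because score scales are
caller-specific).

## Synthetic data generator

The generator emulates the structure of a three-caller endometrial
validation study. Candidate sites draw features independently:

* depths: shifted negative binomial, tumor mean 90, normal mean 60,
  dispersion 5 (coefficient of variation ≈ 0.45, typical of exome
  capture);
* tumor VAF of true mutations: Beta mixture, 70% clonal (mean 0.35) and
  30% subclonal (mean 0.15), concentration 40;
* tumor VAF of artifacts: Beta(1.2, 18) — concentrated near zero with a
  heavy tail;
* normal VAF: near zero for true somatic mutations, slightly elevated
  for artifacts;
* substitution types: C>T/G>A-dominant frequencies as in hypermutated
  endometrial tumors.

Each caller calls each site independently given truth and features: the
call probability is its base sensitivity (true sites) or one minus its
base specificity (artifacts) shifted on the log-odds scale by
feature-dependent modifiers (e.g. sensitivity falling with low depth or
low VAF). A caller with filter models additionally requires every
filter to pass; filters fail with truth- and feature-dependent
probabilities, and quality scores are linear in truth and tumor VAF
plus Gaussian noise. Sites with zero calls are discarded (union
ascertainment). All randomness flows from one seed through named
substreams, so adding a caller never perturbs the others' draws.

Default conditions were calibrated analytically (via the closed-form
ascertainment oracle below) to the published study shape: ~8,400
candidates at 41.5% candidate prevalence yield ~4,400 ascertained sites
at ~78% validation rate, with marginal caller operating points near
(68, 96), (33, 63) and (4, 66) percent FP/TP. Two presets support the
stochastic guarantees: *complementary* (two callers strong on opposite
depth regimes plus a mediocre one — the regime where feature-weighted
stacking beats every individual caller) and *planted-filter* (false
calls concentrated in one filter's fail state while a second filter
fails indiscriminately — the regime where filter-aware refinement beats
quality-only ranking).

For modifier-free ("homogeneous") profiles the per-status masses and
validation rates have a closed form from products of per-caller call
probabilities given truth, renormalized over nonzero statuses; the
simulator is tested against it by chi-square goodness of fit at
n = 50,000.

What the generator does **not** model: read-level errors, mapping
artifacts, shared error modes beyond an optional common-artifact
log-odds shift, patient structure, and realistic joint feature
distributions. Passing tests on this generator therefore demonstrate
the correctness and the qualitative behavior of the combiners, not
their quantitative performance on real tumor data.

## Problem sizes used in tests

Stochastic test batteries run at reduced size so the full suite stays
fast: the dominance and refinement batteries use presets with 3,000
candidate sites per seed (≈2,000 ascertained; 20 seeds each), and the
sparse-recovery battery uses n = 20,000 with an independent Gaussian
111-column design, which isolates estimation error from the collinearity
of the real status/interaction design. Unit tests use a 4,000-candidate
default dataset. Solver tolerances in the batteries are 1e-6 (path) and
3e-6 (CV folds), per-sample.

## Known limitations

* The refinement model assumes filter flags are available for the whole
  candidate universe of the refined caller.
* The 1-SE coefficient bias noted above means selected-λ coefficients
  should be interpreted as a ranking model, not as unbiased effect
  estimates.
* No elastic-net or grouped penalties; no continuous caller-score
  stacking outside the refinement module; no indel or structural-variant
  support.
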