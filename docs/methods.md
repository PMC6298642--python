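# Methods

## Data model

An EP-pair dataset is an ordered list of (enhancer, promoter) candidate
pairs — BED-convention 0-based half-open intervals on one chromosome, a
promoter identifier, and a binary interaction label — aligned row-by-row
with a feature matrix whose columns are tagged E (enhancer), P (promoter)
or W (window).  The window of a pair is the open gap between the two
elements, `[min(ends), max(starts))`; it excludes both elements, and
adjacent elements (zero-width gap) are rejected.  Strand is ignored.
Promoter identity is an explicit column so the group structure is
auditable; a helper can assign IDs by exact promoter-interval identity
when the column is absent.

## Synthetic generator

The generator emulates the three structural properties that make naive
cross-validation of EP classifiers unreliable, with the simplest
mechanisms that produce them:

1. **Shared promoter features.**  Each promoter draws one standard-normal
   latent vector (one value per mark, 136 marks per region by default);
   every pair of that promoter carries it verbatim in the P block.
2. **Shared window signal.**  Each chromosome and mark has a
   piecewise-constant standard-normal latent track (50 kb segments by
   default); a pair's W feature is the track average over its window, so
   two windows correlate in proportion to their overlap (≈1 at full
   overlap, ≈0 when disjoint).
3. **Imbalanced promoter groups.**  Group sizes are `1 + Geometric`
   (mean 8, support ≥ 2, capped at 30).  In the default `pure_mixture`
   profile each group is entirely positive with probability 1/21 and
   entirely negative otherwise — the most contaminating configuration,
   with a 1:20 expected global class ratio.  The `beta` profile instead
   draws each group's positive fraction from Beta(0.2, 4.0) and its
   positive count binomially, producing mixed, mostly ≥2-fold-skewed
   groups.

The E block is one standard-normal latent per enhancer.  The only genuine
feature–label association is a mean shift `signal_strength` (δ) added to
the first `n_signal_features` (16) E columns of positive pairs; **δ = 0 by
default**, so the label is conditionally independent of every feature
given promoter identity, and any above-chance score under a leakage-free
partition would indicate a bug (this null calibration is tested).
Optional iid noise (`feature_noise_sd`, default 0) can blur the
otherwise bit-identical sharing.

Geometry: 5 chromosomes of 50 Mb; 2 kb promoters placed uniformly at
random (rejection-sampled so no two elements overlap); 1 kb enhancers on
a random side of their promoter at gaps drawn **log-uniformly** between
10 kb and 2 Mb.  The log-uniform choice reflects the heavy-tailed distance
distribution of real EP candidate pairs and keeps window-overlap chains
local: uniform gaps would tile each chromosome into a single connected
window-overlap cluster, leaving no admissible boundaries for
position-sorted cross-validation.  With the defaults a dataset has
~3000–3500 pairs and 20–35 sharing units, comfortably supporting 10
chromosomal folds.

Everything derives from a single seeded PRNG: the same configuration and
seed reproduce a dataset bit-for-bit.

### What the generator does not emulate

Feature values are Gaussian latents, not ChIP-seq/DNase signal: no mark
identities, no signal-magnitude realism, no distance–label correlation,
no Hi-C resolution artifacts beyond the group structure itself.  Passing
benchmarks on these data show that the *evaluation machinery* behaves as
claimed (leakage inflates random-CV scores; clean CV recovers planted
signal and calibrates at chance on null data); they say nothing about how
much genuine signal real epigenomic features carry.

## Leakage audit

The audit is structural — computed from coordinates and labels, never
from feature values.  Promoter groups partition the pairs; the sharing
matrix counts groups (promoter-weighted) or their pairs (pair-weighted)
by (n_pos, n_neg), the two weightings related cell-by-cell by a factor
(n_pos + n_neg).  A group's *contamination accuracy*
`max(n_pos, n_neg)/(n_pos + n_neg)` is the test accuracy of a
promoter-memorizing majority rule — ≥ 0.5 always, exactly 1 on pure
groups, 7/9 ≈ 78% at (7, 2).  Imbalance classes use a 2-fold threshold;
a zero count on either side counts as infinitely skewed, since pure
groups are the most contaminating.  The leaky-pair fraction counts pairs
in groups that both share a promoter (size ≥ 2) and are ≥ 2-fold skewed.
Window-overlap components are connected components of the
positive-overlap graph on windows, computed by a per-chromosome sweep
(exact for interval graphs) and verified against a brute-force transitive
closure in the tests.

## Cross-validation schemes

* **random** — pairs shuffled by seed and dealt into k folds (sizes
  differ by ≤ 1).  Unstratified: the reference formulations used plain
  random assignment.
* **chromosomal** — pairs sorted by (chromosome in natural order, window
  midpoint, pair_id).  Fold boundaries may only fall where no promoter
  group and no window-overlap component straddles the cut; among
  admissible placements, a dynamic program picks the k contiguous blocks
  minimizing the sum of squared fold sizes.  Deterministic, and certified
  to have zero cross-fold promoter links and zero cross-fold window
  links.  Balance is best-effort: when the largest indivisible sharing
  unit exceeds ~2·n/k (which happens at the default geometry, where
  window chains can reach ~450 pairs), no placement can keep fold sizes
  within 2-fold of each other; the DP is provably optimal among
  admissible placements and the tests verify optimality by brute force on
  small fixtures.
* **promoter_segregated** — whole promoter groups shuffled by seed and
  dealt greedily to the currently smallest fold.  Eliminates promoter
  leakage by construction but can still split window-overlapping pairs
  of different promoters — exactly the residual contamination channel the
  certificate exposes.

`certify` counts, exactly, the unordered pairs of EP pairs that share a
promoter or overlap windows while sitting in different folds (grouped
counting for promoters, per-chromosome vectorized overlap for windows);
it is validated against a quadratic double-loop oracle.  k defaults
to 10.

## Benchmark harness

For each fold the model is fit on the remaining folds and scored on both
splits.  Tree families consume raw features; SVM families see features
standardized with training-fold statistics only (without which RBF
kernels on unscaled features are degenerate).  Scores are positive-class
probabilities for tree models and logistic-squashed decision values for
SVMs, so the fixed 0.5 threshold used for precision/recall/F1 coincides
with each model's native class prediction while AUROC/AUPRC use the raw
ranking (ties averaged).  Folds holding out a single class get NaN
ranking metrics and a warning.  Per-fold model seeds derive
deterministically from a run seed.  Results are reported per fold, as
fold averages, and pooled over the concatenated held-out predictions.

Gradient boosting defaults to scikit-learn's histogram-based
implementation (`max_iter` trees, early stopping disabled) for speed,
with the classical exact implementation available via
`tree_method="exact"`; random forest, RBF SVM (default C = 1,
γ = 1/n_features) and linear SVM complete the scan families.  All other
hyperparameters stay at scikit-learn's documented defaults.

Analytic baselines: `f1_score(p, r) = 2pr/(p+r)` (0 at p = r = 0) and the
all-positive baseline `2p/(1+p)`, equal to 1/11 at prevalence 1/21 — the
"random" floor used when judging imbalanced test scores.

## Problem sizes and numerical choices

The full-scale demonstration (acceptance script and end-to-end tests)
uses the generator defaults — ~400 promoter groups, ~3000–3500 pairs,
408 EPW features — with 4000-tree gradient boosting under random and
chromosomal 10-fold CV; one such run takes a couple of minutes on one
CPU.  Unit and property tests use scaled-down configurations (tens to a
few hundred promoters, 12–40 marks, shorter `max_distance` where
fragmented sharing units are needed) chosen so each statistical assertion
has Monte-Carlo error well inside its tolerance.  In particular, the
null-calibration check (mean clean-CV AUROC in [0.45, 0.55] on
zero-signal data) averages over six generator seeds with small promoter
groups: scores are near-identical within a group, so the effective sample
size per fold is the number of groups, and single-fold AUROC on
default-sized groups swings widely around 0.5 (a property of the
evaluation, not a bug — the corresponding F1 stays at the floor).

Known limitations: the generator's sharing is all-or-nothing at the
promoter (real promoter features vary slightly across assays/versions);
window correlation decays linearly with overlap at the 50 kb track scale
rather than following real signal autocorrelation; chromosomal fold
balance degrades when sharing chains are long relative to n/k; and the
harness is deliberately restricted to the four classical model families
used in the parameter scans.
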