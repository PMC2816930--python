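# Methods

## Model and assumptions

Dual-KS treats discriminant gene selection as the mirror image of gene set
enrichment analysis. In GSEA one sample's genes are ordered by expression
and a *gene set* is tested for clustering at an extreme of the list; here
one gene's *samples* are ordered by that gene's expression and a *sample
class* is tested for clustering at the top or bottom. Both steps use the
same Kolmogorov–Smirnov running-sum statistic, hence "dual".

For gene `i` and class `l` with `N_l` of `N` samples, the decreasing-order
running sum gains `N/N_l` at class-`l` samples and loses `N/(N−N_l)`
elsewhere; it always terminates at 0, and its maximum `u_il ∈ [0, N]` is
the up-regulation score. The increasing order gives `d_il`; with distinct
expression values `d_il = −min` of the decreasing-order running sum.
`u_il/N` is exactly the one-sided two-sample KS distance `D⁺` between the
class and non-class expression ECDFs — the scores are purely rank-based,
so any strictly monotone per-gene transform (log, quantile normalisation)
leaves them unchanged. The method assumes nothing about the expression
distribution; what it does assume is that class identity expresses itself
as a *location* bias of one class's samples within each informative gene's
ordering.

Selection uses the penalised differences `U^Δ = U − D` and `D^Δ = D − U`.
A gene whose class samples sit half at the top and half at the bottom of
the ordering scores high on both `u` and `d` — the worst possible
classifier gene — and the difference cancels it. Each class receives the
`t` best genes per direction, equal sizes by design so that every class
carries the same weight at classification time.

## Scoring variants

- **default** — raw `u`/`d` scores.
- **weighted** — `w_il = −log(R̄_il/G)` with `R̄_il` the rank (1 = largest)
  of gene `i`'s class-`l` mean among all `G` genes; `û = w·u`,
  `d̂ = (1−w)·d`. The weight prefers genes that are high in absolute terms,
  which matters because classification ranks signature genes *within* a
  sample. Note `1 − w < 0` for top-ranked genes when `G ≥ 3`: the formula
  is applied exactly as defined, so strongly expressed genes are actively
  penalised as down-signature candidates rather than clamped to zero —
  clamping would silently change selection. The logarithm base (default:
  natural) is configurable because it cancels in the ranking of `û` but
  not of `d̂`.
- **rescaled** — signatures are selected from the raw scores; at
  classification each class's enrichment score is divided by `r_l`, the
  maximum combined score of that class's signature over the training
  samples, constraining training scores to (0, 1]. A non-positive `r_l` is
  refused with an error (a negative normaliser would silently invert the
  argmax); the default variant is the fallback.

## Classification

The pooled signature holds `n = t×K` *slots*, each slot one gene tagged
with its owning class. Up-slots are ordered by decreasing sample
expression, down-slots increasing; class `l`'s running sum gains `n/n_l`
on its own slots (`n_l = t`) and loses `n/(n−n_l)` otherwise, giving
`u′_l` and `d′_l` as maxima and `E_l = u′_l + d′_l` (single term in
up-only/down-only modes, `/r_l` when rescaled). The sample is called as
the argmax class; exact ties are broken by model class order and flagged.

Slot ownership, rather than plain set membership, decides the increment.
The two rules coincide whenever class signatures are disjoint (the usual
case); when a gene is shared between two classes' signatures, ownership
keeps every class at exactly `t` positive slots so each running sum still
terminates at 0 and `n_l = t` holds exactly.

Signature genes missing from a new dataset are a hard error by default;
the opt-in policy drops a missing gene from *all* classes' signatures and
recomputes `n` and the per-class `n_l`, because dropping asymmetrically
biases scores toward the unaffected classes.

## Error estimation and signature size

The 0.632+ bootstrap blends the resubstitution error `err_train` with the
leave-one-out bootstrap error `err1` (per-sample average over replicates
where the sample is out-of-bag). With the no-information rate
`γ = Σ_l p_l(1−q_l)` (`p_l` class priors, `q_l` the full-data model's call
proportions), the relative overfitting rate is
`R = (err1 − err_train)/(γ − err_train)` clipped to [0, 1], the weight
`ŵ = 0.632/(1 − 0.368·R)`, and
`err632+ = (1−ŵ)·err_train + ŵ·min(err1, γ)`.

Every replicate refits the complete model — scoring, weighting ranks, gene
selection, rescale factors — on the in-bag samples only; nothing derived
from out-of-bag samples enters training (a test corrupts the out-of-bag
columns and asserts the replicate model is unchanged). Resampling is
stratified within class by default (`B = 100` replicates); plain
resampling is available, with replicates that lose an entire class redrawn
up to a budget.

The signature-size sweep runs the estimator over a grid of `t` (presets:
`coarse` = 5..50 step 5 for readable variant comparisons, `fine` = 1..50
when the single best size is wanted) with a shared seed so all grid points
see identical bootstrap draws, and selects the error-minimising `t`. Ties
take the smallest `t`: parsimony is the point of the method. The sweep
defaults to up-only signatures, the convention for size selection;
per-variant optima are reported separately when several variants are
swept. In practice the error curve flattens or rises beyond the
informative gene set — large signatures dilute signal with noise genes —
which is exactly what the sweep is meant to reveal.

## Synthetic data

The generator emulates a log-scale expression matrix: per-gene baselines
`Normal(7, 2)`, per-sample noise `Normal(0, 1)`, and for each class a
reserved block of informative genes shifted by ±`effect`·SD in that
class's samples. Defaults — 200 genes, 3 classes, 20 samples per class, 5
informative genes per class per direction, effect 5 — describe a
desk-scale multi-class study with near-zero Bayes error, so failures of
recovery or accuracy indicate algorithmic faults rather than sampling
noise. Gene blocks are assigned deterministically from gene order, so
independent draws (different seeds) share the same ground truth and serve
as train/test pairs.

What the generator does **not** emulate: probe/platform effects, batch
structure, heavy-tailed or count noise, correlated gene modules, tied
values, and class-imbalanced designs (sizes can be varied, but the tests
use balanced ones). Passing tests therefore demonstrate correctness of
the algorithmics and calibration under clean rank signal, not robustness
to real microarray artefacts. The lognormal option exponentiates the same
latent matrix — a monotone transform, so all scores are identical to the
normal case by construction; it exists to exercise raw-scale input paths.

## Numerical conventions

- Ties in expression are broken by sample identifier (scoring) or gene
  identifier (classification, rank weights, signature selection),
  ascending, after the value key; results are deterministic but
  convention-dependent under ties, which the scores' rank-based definition
  cannot avoid. Heavy-tie data (raw counts) is better pre-jittered or
  handled on a rank-transformed scale chosen by the user.
- NaN/Inf expression is rejected at load time; no imputation.
- Running sums terminate at 0 within 1e-9 (sums of `N` rational
  increments); `U^Δ = −D^Δ` asserted at the same tolerance; exact
  classification ties flagged at 1e-12.
- Selection-score ties at the signature boundary are broken by gene id,
  which also makes the `t`-gene signature a prefix of the `t+1`-gene one.
- All randomness (simulation, bootstrap) flows through
  `numpy.random.default_rng(seed)`; a seed fully determines every draw,
  and sweep grid points reuse the seed so they share draws.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use the generator defaults:
1200 random oracle draws; 20 simulations for recovery/accuracy with an
independent 60-sample held-out draw each; one `B = 100` null-calibration
estimate on 40 permuted-label samples; 10 sweeps over 5..50 step 5 at
`B = 100`. These sizes give stable Monte-Carlo estimates at desk scale
(the full set runs in about a minute on one core).

## Known limitations

- No per-gene significance is attached to `u`/`d` scores, and no
  probability calibration to `E_l`; the classifier has no reject option.
- The `1 − w` factor of the weighted variant can leave down-signatures
  dominated by low-expressed genes when `G` is small.
- Bootstrap error estimates at very small `N_l` are noisy even stratified;
  the estimator is reported with all components so the user can judge.
- Cross-class signature overlap is allowed; heavily overlapping signatures
  indicate the classes are not separable by this score and should be
  interpreted accordingly.
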