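# Methods

This note documents the models and procedures implemented in `unitcause`,
their assumptions, the defaults that matter, and what the synthetic
cohorts do and do not establish about real data.

## The synthetic cohort generator

Because the motivating pediatric-myopia cohort is not publicly deposited,
all development and testing runs against cohorts drawn from a documented
structural causal model (`unitcause.cohort`). The generator emulates:

- the 16-feature schema (10 continuous, 5 discrete/ordinal, 1 binary)
  with marginals placed inside the published ranges. The published range
  for K2 (38–183 mm) is physiologically implausible for corneal
  keratometry; the default spec uses a K1-like range (38–71);
- the published causal skeleton: PWG, GENDER, NAR, DAR, K1 and K2 are
  direct causes of both axial length (AL) and cycloplegic refraction
  (CR); HEIGHT and REDM cause AL only; AL causes CR; CB, EGG, NW, PULSE,
  WHIM and DTO are isolated. 15 directed edges over 10 connected
  variables;
- the clinical labelling rule: myopia ⇔ CR ≤ −0.5 D (threshold
  included).

Sources are sampled from documented normal/categorical marginals;
children are **linear in their parents plus Gaussian noise** — the same
linearity the mediation analysis assumes, so path-product oracles are
exact. Default coefficients (natural units, one table in
`cohort.DEFAULT_EDGE_COEFF`) follow the qualitative clinical directions:
AL→CR is −0.90 D/mm (longer eyes are more myopic), HEIGHT→AL is
+0.030 mm/cm, parental myopia and male gender lengthen AL. The NAR/DAR
coefficients into CR are negative; with positive signs the direct
NAR→AL effect and the correlation induced by conditioning on the
collider-child CR cancel almost exactly (partial correlation ≈ 0.005),
an unfaithful parameterization under which no constraint-based method
can recover the edge. The CR intercept (36.25) puts the myopia rate near
41%, keeping both classes trainable.

Range clipping is **off** by default: clipping would break the
linear-Gaussian form every estimator and oracle relies on.

What passing tests on these cohorts shows: the estimators recover the
quantities they target when their assumptions (linear mediation, no
latent confounding, faithfulness) hold. What it does not show: behavior
under non-linear mediation, missing data, measurement error, or hidden
confounders — none of which the generator emulates.

## Causal discovery

Classical PC with a degenerate-Gaussian likelihood-ratio CI test
(`unitcause.discovery`):

- **Embedding.** Continuous columns standardized; each discrete/binary
  column one-hot encoded with the lowest level as the dropped reference.
- **Test.** For blocks X, Y given Z, the Gaussian LR statistic
  `n·(log det R(Y|Z) − log det R(Y|Z∪X))` referred to χ² with
  `dim(X)·dim(Y)` degrees of freedom. The two regression directions are
  algebraically identical (Schur determinant identity), so the
  symmetrized p-value (min of both directions, Bonferroni factor 2)
  reduces to doubling one p-value; measured type-I error at nominal 0.05
  is ≈ 0.02–0.05, inside the accepted [0.01, 0.10] band. All tests are
  computed from one embedded covariance matrix, so each CI test costs
  O(d³) in the block dimension, independent of n.
- **Search depth.** Unbounded by default (classical PC termination), with
  an automatic cap when the sample cannot support a conditioning set's
  embedded dimension (warned). A fixed small cap is tempting at 16
  variables, but separating HEIGHT or REDM from CR in this graph requires
  conditioning sets of size 7 ({AL} plus the six common parents, because
  conditioning on the collider AL opens HEIGHT→AL←P→CR paths), so any
  cap below that provably leaves two extra edges.
- **Orientation.** Unshielded colliders from recorded separating sets
  (conflicting demands leave the edge undirected), then Meek rules R1–R4
  to closure. Remaining undirected edges are reported as undirected and
  excluded from path-based attribution with a warning, never arbitrarily
  oriented. Orientation is asserted never to create a directed cycle.
- **Determinism.** Lexicographic variable and subset ordering everywhere
  PC is order-dependent.
- **PCA switch** (off by default): groups of continuous columns with
  |r| > 0.95 are replaced by principal-component scores *for testing
  only*; the graph is always over the original names.

At the study's own scale (n ≈ 2700, α = 0.05) recovery is good but not
perfect (structural Hamming distance typically ≤ 7 of 15 edges); at
n = 20000, α = 0.01 the full structure is recovered (SHD ≤ 4) in ≥ 80%
of seeds. Attribution therefore runs on a *fixed* analysis graph (the
published structure or a user-supplied edge list) when one is available,
mirroring the original workflow where discovery and attribution are
separate stages.

## The classifier

A 16-12-8-2 ReLU network with softmax output, trained by mini-batch SGD
on cross-entropy (`unitcause.nn`). Defaults: learning rate 0.01, batch
32, 200 epochs, no regularization — the original tuning protocol was not
reported, so these are package choices, documented and overridable.
Inputs are standardized with training statistics inside the model.
Metrics (accuracy, sensitivity, specificity, F1, AUC) are reported as
mean ± SD over five random 80/20 splits.

Because the hidden layers are piecewise linear, the logits are locally
affine, giving an exact local Hessian of each class probability
(softmax curvature conjugated by the local Jacobian); a central
finite-difference Hessian (step 1e−3 on the standardized scale) serves
as an independent cross-check. Points on a ReLU kink are nudged by 1e−6
with a warning. Attribution uses the post-softmax class probability by
default; a logit mode exists behind a flag.

## Isolated and Pure attribution

The intervention expectation is approximated by the second-order
expansion `E[y|do(x_i=α)] ≈ f(μ′) + ½·tr(∇²f(μ′)·Σ′)` where (μ′, Σ′) are
the intervened moments. The do-update is the congruence
`Σ′ = (I − t e_uᵀ) Σ (I − t e_uᵀ)ᵀ` with t the unit's total-effect vector
(t_u = 1; for Isolated units t = e_u): it zeroes the intervened row and
column, removes exactly the variance each mediator receives through the
unit, is positive semidefinite by construction, and is exact for source
units of a linear SCM. Downstream means shift by
`total effect × (α − old mean)`, with total effects as path sums of
products of OLS edge coefficients (each node regressed on all its
parents jointly).

Curves sweep a uniform grid (default 10 points) between the unit's 1st
and 99th cohort percentiles — not the schema extremes, to avoid
extrapolation; binary units get the exact {0, 1} grid. The reported
`ace` is the grid average of the expectation (uniform-grid quadrature of
the interval-averaged ACE); the curve minus its own mean ("centered") is
the display quantity; `span_effect` (top-of-grid minus bottom) is the
binary contrast `E[y|do(1)] − E[y|do(0)]` on a two-point grid. The
continuous ACE definition is an *average level*, not a contrast — the
binary formula is recovered as the span, and tests pin both readings.

**Validity regime.** The expansion assumes f is smooth over the
perturbation support. An `activation_margin` diagnostic measures the
distance from the expansion point to the nearest ReLU kink in
perturbation SDs; the Taylor value matches a 10⁵-draw Monte-Carlo oracle
within 3 MC standard errors whenever the margin is ≥ 6 at per-coordinate
SD ≈ 0.02. On classifiers trained against a deterministic threshold
label the decision boundary is sharp and the trace term explodes near
it, so the curve engines default to `method="auto"`: Taylor when the
margin is ≥ 3, otherwise exact sampling of the intervened Gaussian
(common random numbers across the grid, 20000 draws, seeded). `"taylor"`
and `"mc"` can be forced.

## Confounded attribution

For a unit with parents among the inputs, each adjacent pair of
discretized groups (default 10; equal-width `linspace(min, max, k+1)`
edges, or equal-frequency with rank-based assignment so group sizes
differ by ≤ 1) defines a binary treatment among the records in either
group. The adjustment set is the unit's parents — always a valid
backdoor set in a DAG without latents, verified by d-separation on the
outgoing-edge-pruned graph. The model's outcome node enters the graph as
a child of CR only, since the label is a deterministic function of CR.

The estimator is an R-learner: cross-fitted logistic propensity ê
(clipped to [0.01, 0.99]; > 20% of scores at the bounds triggers a
positivity warning), outcome nuisance m̂ = ê·m̂₁ + (1−ê)·m̂₀ from
per-arm gradient-boosted models trained with inverse-propensity weights
(the "domain-adaptive" reweighting — no further transfer machinery),
then τ̂ minimizing Σ w·[ψ − τ̂(x)]² with ψ = (Y−m̂)/(T−ê), w = (T−ê)².
τ̂ is the convex 10:1 combination of a gradient-boosted-tree and a
random-forest learner, applied at the prediction level. Cross-fitting
uses 5 stratified folds throughout. The outcome defaults to the
classifier's class probability (variance reduction); a flag switches to
the hard label.

`R score = 1 − L̂_R/L_base` is computed by refitting τ̂ per
cross-validation fold and evaluating the held-out R-loss; the baseline
replaces τ̂ with the training fold's weighted constant effect, so the
constant-effect model scores exactly 0 by construction.

Per-pair ACEs are reported with the cumulative curve benchmarked at 0.
Degenerate extreme groups (possible under equal-width binning of
Gaussian-tailed units) raise; equal-frequency binning avoids them.

## Refutation

Five falsification strategies, each averaged over repetitions (default
20) from a shared seed stream: bootstrap resampling, appended
standard-normal common-cause columns (1 per repetition by default),
random subsampling (fraction 0.8), permuted treatment, and
standard-normal dummy outcome. Error rates are `|new − est|/|est|` for
the three stability strategies and `|new|` for the two nullity
strategies. Pass thresholds: 10% relative (the published bar) and 0.05
absolute on the probability scale (the absolute bar is a package choice;
both configurable). A zero base estimate makes the relative errors
undefined; this is flagged rather than silently passed.

## Numerical choices and degenerate inputs

- CI tests floor residual-covariance eigenvalues at ~1e−12 so exact
  functional dependence yields a huge finite statistic (p → 0); a block
  that is singular *given the conditioning set alone* raises a
  collinearity error. Constant columns are rejected at embedding.
- Singular conditioning blocks fall back to pseudo-inverse with a
  warning; collinear parent sets in edge-coefficient OLS likewise.
- Sample covariances use the 1/n convention; summaries require
  n ≥ p + 1.
- Problem sizes in the test suite and acceptance script (cohorts of
  2748–20000, 10–20 replicate seeds, 10⁵-draw oracles) were chosen so
  every stochastic check has comfortable statistical margin while the
  whole suite runs in minutes on one core.

## Known limitations

- Mediation is linear; non-linear mediation is out of scope by design.
- The Taylor expansion is unreliable near sharp decision boundaries
  (see validity regime above); the sampling fallback is exact for the
  Gaussian-summary semantics but inherits that summary's Gaussianity
  assumption.
- No latent-variable machinery (PAGs, FCI): the backdoor arguments
  assume causal sufficiency.
- The generator's deterministic label (myopia as a hard CR threshold)
  makes the classification task easier than real cohorts, where label
  noise would smooth the learned boundary.
- Whether the outcome should participate in discovery is ambiguous; the
  package excludes it (discovery runs on the 16 features only) and
  attaches it to CR for identification queries.
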