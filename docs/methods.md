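# Methods

## Scope and model

`irtscore` scores respondents on a fixed, previously calibrated
polytomous IRT model (a "common metric") spanning items from several
questionnaires. Two model families are supported, one per metric:
Samejima's graded response model (GRM) and Muraki's generalized partial
credit model (GPCM), both with the logistic link and a bank-level
scaling constant D (default 1.0; banks calibrated with the
normal-ogive-approximating convention can set `scaling_D: 1.7`). The
package never re-estimates item parameters: banks are read-only inputs,
and all person-parameter estimation conditions on them. This separation
is what makes scoring valid item-subset by item-subset — a respondent's
likelihood is the product over *answered* items only, so missing
responses (or administering just one instrument of the metric) simply
remove factors rather than invalidating the model.

Item banks are JSON documents in the discrimination/threshold
parameterization; a loader option converts slope–intercept input
(b_k = −c_k/a), since both conventions circulate in the linking
literature. Raw response codes are mapped to internal categories
0..K−1 per item (not per instrument), because linked instruments mix
category counts. Data ingestion is deliberately strict: CSV columns
match item codes exactly and case-sensitively; everything else is
dropped and reported; unmappable cell values become missing and are
counted, never coerced.

## Estimators

All estimators work on the latent scale and search/integrate over
[−6, 6] by default (the model itself is defined on all of ℝ; the bounds
are numerical working ranges, configurable).

**Pattern EAP** (default, with the standard normal prior): posterior
mean and SD on an equally spaced quadrature grid, default 101 nodes,
weights proportional to the prior density renormalized over the grid.
An equally spaced grid rather than Gauss–Hermite keeps weights
elementary and lets the same nodes serve every respondent and the EM
prior estimation. With 101 nodes the discretization error is well below
the reporting precision (the test suite checks agreement with a
10,001-node reference to 1e-3); callers can raise `n_nodes`. For an
all-missing pattern the posterior is the prior, so the prior mean and
SD are returned exactly, flagged `ALL_MISSING`.

**Sum-score EAP**: the probability of each total score at each node is
assembled by the Lord–Wingersky convolution recursion over items; the
posterior over θ given the observed total yields the estimate and SE.
The item set must be one instrument answered completely
(`INCOMPLETE_FOR_SUMSCORE` otherwise): sum scores are
instrument-specific quantities, and mixing partially answered sets
would make the total's distribution ill-defined.

**MAP**: safeguarded Newton on the posterior score (analytic first and
second derivatives; the log-posterior is concave for both families
under a normal prior, so the root is unique). SE from the curvature of
the log posterior at the mode.

**ML**: same Newton machinery on the log-likelihood. Divergence is
detected structurally — all answered responses in the lowest (or all in
the highest) category make the likelihood monotone, so the estimate and
SE are returned missing with `DIVERGED` — plus a gradient check at the
search bounds (`AT_BOUND` when the optimum sits on a bound with nonzero
gradient). SE = 1/√I(θ̂) with Fisher (expected) test information.

**WLE**: Warm's weighted likelihood, the root of
score(θ) + J(θ)/(2I(θ)), where I = Σ_items Σ_k P′²/P is the expected
information of the answered items and J = Σ Σ P′P″/P its companion sum,
both analytic. The weighted score can have several downward zero
crossings when GPCM steps are strongly unordered; the solver scans a
241-point grid, ranks crossings by the antiderivative of the weighted
score (the integrated weighted objective) and refines the global one by
safeguarded Newton. The Newton slope uses the log-likelihood curvature
— the dominant term near the root — with a maintained sign-change
bracket and bisection fallback covering the approximation.

Root finding throughout: Newton with an enforced bracket, bisection
fallback, |Δθ| < 1e-6, at most 100 iterations. Probabilities are
floored at 1e-300 before logs and divisions; extreme θ with steep
slopes would otherwise underflow.

## Priors

Standard N(0,1), diffuse N(0,10) — interpreted as **variance** 10
(SD √10), the mean/covariance convention of mainstream IRT software;
both mean and variance remain explicit on the `Prior` object for users
who intended SD 10. The empirical prior estimates a normal mean and
variance by EM with item parameters fixed: E-step = each respondent's
posterior node weights under the current prior, M-step = posterior-
weighted sample moments, stopping when both parameters move < 1e-4 or
after 100 iterations. A normal family (rather than an empirical
histogram) was chosen as the simplest shape consistent with reporting a
mean/variance pair; the histogram alternative is noted as future work.
Below 50 usable rows the estimate is too unstable to trust, so the
function warns and falls back to N(0,1).

## Reporting

T = 50 + 10·θ and se_T = 10·se; the transform is affine and invertible,
and missingness propagates (diverged ML rows stay missing with their
flags rather than being clamped). Descriptive statistics cover
non-missing T scores: n, min, mean, median, max, SD (ddof 1),
SEM = SD/√n, percent missing; histogram bin edges use Freedman–Diaconis
with a floor of 5 bins. Precision curves report
SE(θ) = 10/√I(θ) per item set on a shared grid and carry the annotation
"valid under ML estimation only", since Bayesian estimators' standard
errors include prior shrinkage that the information function ignores.
T scores are exported unrounded by default with an optional 1-decimal
rounding for CSV output.

## Synthetic data

The generator stands in for the published metrics, whose parameter
values live in their source publications. The default bank mirrors the
shape of a two-instrument depression metric — 9 + 7 items (PHQ-9 /
GAD-7 scale sizes), four categories each, GRM — with discriminations
uniform on [0.8, 2.5] and thresholds sorted uniform draws on
[−2.5, 2.5], ranges typical of published PRO calibrations. Respondents
draw θ from a normal population and responses from the model's category
probabilities; missingness is MCAR at a configurable rate (sufficient
to exercise missing-data tolerance; informative missingness is out of
scope). True θ is returned separately and never written into the
response table, so scoring code cannot leak it. Everything is
deterministic under an explicit seed.

What the generator does *not* emulate: differential item functioning,
local dependence between items of one instrument, response styles, or
non-normal trait distributions. Passing tests therefore demonstrate the
estimation machinery's correctness under the model, not the validity of
any particular published calibration on real data.

## Problem sizes and tolerances in the checks

The acceptance script and tests use: 50 randomized banks (≤ 10 items,
K ≤ 5) against 10,001-node dense-grid references (agreement to 1e-3);
exhaustive pattern enumeration on a 4-item bank against the
Lord–Wingersky recursion (1e-8); 2,000 simulated respondents for
population-recovery checks (empirical prior mean within ±0.1, variance
within [0.85, 1.15]); and 2,000 replicates at θ = 1 on the 9-item
instrument for the WLE/ML bias comparison. These sizes give
Monte-Carlo error comfortably below the asserted margins while keeping
a full run in the tens of seconds.

## Known limitations

- Unidimensional models only; no testlet/bifactor structure, no
  non-logistic links.
- No plausible values or other propagation of scoring uncertainty into
  secondary analyses.
- The empirical prior is a single normal; multimodal samples are
  summarized by their first two moments.
- `AT_BOUND` estimates are reported at the working bound; users scoring
  populations routinely beyond |θ| = 6 should widen the bounds.
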