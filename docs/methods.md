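# Methods

This note records the models implemented in `pomarch`, their assumptions,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Shoot types and inputs

A first-order apple branch carries three shoot types.  A mixed bud develops
into a spur: a short shoot (the *bourse*) bearing preformed rosette leaves
(RO) and one or two sylleptic *bourse shoots* (BS); a vegetative bud
develops into a *vegetative shoot* (VS) with preformed plus neoformed
leaves.  All leaf-area models take exactly two per-shoot inputs — the leaf
count `nl` and the longest-leaf blade length `Lmax` (cm) — because these
are the traits that can be scored quickly and non-destructively in an
orchard.  Units are cm and cm² throughout; only ratios enter the models, so
the unit convention is a presentation choice.

## Blade geometry

Blades are modelled as ellipses: area A = πLW/4 with length L on the major
axis.  Within one shoot type and genotype the width/length ratio
k = W/L = √(1 − e²) is treated as constant; it is estimated by
through-origin least squares of W on L (the ratio model has no intercept).
Records with W > L are rejected, never silently swapped — the caller must
assign the major axis.  Eccentricity noise in real blades makes k̂ a
slightly curved functional of the data; at the default noise level this
contributes a bias of order 0.005, below the 2-decimal resolution at which
k values are reported.

## The Lorentz leaf-area profile and its closed form

Normalized leaf area N(A_R) = A_R/Amax over normalized rank follows

    f(x) = 1 / (1 + (x − x₀)²/s²),   M = 1 after normalization.

Normalized rank is R/nl for rosettes and vegetative shoots.  For bourse
shoots the biggest leaf sits overwhelmingly at rank 2 (the observed
biggest-leaf-rank distribution concentrates 50–88 % of shoots there,
depending on genotype), so the bourse-shoot rank is shifted: x = (R−2)/nl,
which pins the peak at zero without stretching the curve.

The profile is deliberately **not** fitted to the noisy normalized scatter.
Instead, the robust total-area allometry TLA = β·nl·Amax is fitted first
(through-origin least squares of TLA on nl·Amax — the allometry has no
intercept), and s is then obtained analytically from β via the integral of
the profile:

    ∫_a^b f(x) dx = s·[atan((x − x₀)/s)]_a^b = β,

with bounds a = −2/nl, b = (nl−2)/nl for bourse shoots (valid for all
nl ≥ 1, including nl ∈ {1, 2} where the interval lies at or below zero) and
0..1 with x₀ for rosettes.  The left side is strictly increasing in s and
bounded by b − a, so for 0 < β < b − a the equation has exactly one root.
It is solved by bracketed Brent iteration on s ∈ [10⁻⁶, 10³] to
|Δβ| ≤ 10⁻¹⁰; a derivative-free bracketing method was chosen because
monotonicity makes it unconditionally robust.  For bourse shoots s depends
on nl through the bounds, so the fit tabulates s for nl = 1…18 once
(matching the shipped table, which is printed at 2 decimals); leaf counts
beyond the table are solved on demand.

The finite-rank sum Σ_R f(x_R)/nl differs from the integral (the Riemann
gap): computed with the shipped scale values at β = 0.67 the gap is −0.034
at nl = 8, −0.031 at nl = 10 and −0.019 at nl = 18.  This gap is one of the
things the calibration slope α absorbs.

### Rosette peak position x₀

The workflow estimates x₀ (the normalized rank of the biggest rosette
leaf) from training data.  Two estimators are provided:

* `estimate_x0` — the mean of RAmax/nl across rosettes; simple, rank-only.
* `fit_profile_x0` (used by the pipeline) — a free-amplitude Lorentz
  least-squares fit to the pooled normalized (rank, area) scatter.  Each
  shoot's biggest leaf is excluded: its normalized area is identically 1 by
  construction of the self-normalization and therefore carries no
  information about the curve.  The free amplitude makes the estimator
  exact when the data lie on a common scaled Lorentz curve.

With integer leaf ranks the population of shoots cannot share a single
continuous peak position exactly, so the pooled fit carries a small
discretization residual (≲ 10⁻³ at zero noise); this is an intrinsic limit,
not a solver tolerance.

## Calibrated forward models

    BS:  A_R = α·(π/4)·k·Lmax² / (1 + (R − 2)²/(nl²·s(nl)²))
    RO:  A_R = α·(π/4)·k·Lmax² / (1 + (R − nl·x₀)²/(nl²·s²))
    VS:  A_R = p·(R/nl)·(π/4)·k·Lmax²

The non-integer rosette peak rank nl·x₀ is used as-is (the formula is
continuous in the offset).  α is the through-origin slope of measured on
calculated total leaf area on the training set, per shoot type and
genotype; it is applied per leaf, so per-leaf and total predictions carry
the same factor and α cancels in normalized comparisons.  After applying
α, the training-set regression of measured on calibrated-calculated TLA
has slope 1 by construction; testing happens on the held-out third.

The vegetative-shoot model is descriptive (testing data were insufficient
for a calibration stage); p is the through-origin slope of measured leaf
areas on the rank-proportional ellipse term, shipped as p = 0.95 with
k = 0.56 for Ariane/Fuji pooled.

Shipped parameter sets (AR / FU / RB): β_BS = 0.67|0.67|0.50 with the
per-nl scale table; β_RO = 0.69, s_RO = 0.38, x₀ = 0.63 for all genotypes;
k_BS = 0.60|0.64|0.66, k_RO = 0.75|0.74|0.71, k_VS = 0.56;
α_BS = 1.2|0.99|1.87, α_RO = 0.86|0.92|0.92; internode qi = 0.62,
si = 0.12.

## Internode model

Treating the bourse and its bourse shoot as one morphogenetic unit, the
normalized cumulative length from the bourse base to the insertion node at
continuum rank R_I follows a logistic, N(D_I) = 1/(1 + exp((qi − R_I/nl)/si)).
The continuum rank convention: the first bourse-shoot internode takes the
rank of its insertion node plus one.  The model is fitted by nonlinear
least squares on pooled points from all spur continua (per-spur fitting
followed by averaging is an alternative the data description does not
disambiguate; pooling was chosen as the variance-efficient option),
initialized at qi₀ = median normalized rank and si₀ = 0.1 — robust starting
values for sigmoid data on the unit interval.  Degenerate inputs (fewer
than 4 points, no length variation, points on one side of the midpoint)
raise explicit errors.  The fitted curve implies internode lengths that
rise from the short basal bourse zone to a steep median zone and shorten
again subapically.

## Phenology

Growing degree hours of a day are Σ_h max(HT_h − T_b, 0) over exactly 24
hourly readings (base temperature default 7 °C); days with missing hours
are rejected rather than interpolated.  Cumulative growing degree days
from full bloom are Σ GDH_i/24.  The full-development filter retains
bourse shoots from genotype-specific GDD thresholds onwards (defaults
345 / 201 / 275 for AR / FU / RB) and drops rosettes sampled at harvest;
thresholds are configuration, not discovery.

## Parameterization workflow

`run_parameterization` executes, in order: grouping tests → β per genotype
group → s (per-nl table for BS; via x₀ for RO) → k per genotype → training
predictions → α calibration → held-out testing.  Groups are compared on
the per-shoot slope TLA/(nl·Amax): Shapiro–Wilk on within-group residuals
routes to one-way ANOVA (normal) or Kruskal–Wallis, and genotypes are
pooled transitively over pairwise non-significant differences at the 5 %
level.  The default grouping (BS: {AR, FU} vs {RB}; RO and VS pooled) is
explicit configuration; the tests are always run and reported.  No
multiple-testing correction is applied, matching the source workflow; this
is a known limitation.  The random 2/3 : 1/3 train/test split is stratified
by genotype and fully determined by the seed; the same dataset and seed
produce a byte-identical parameter file.  Testing regressions report both
the through-origin slope and the with-intercept slope (the convention the
published slopes used is ambiguous); R² is the squared Pearson correlation
between observed and predicted.

## Synthetic data: what it emulates, and what it cannot

The generator emulates the statistical structure the analysis assumes:
truncated-Poisson leaf counts (means 6 / 5 / 12 for BS / RO / VS on
[2, 18], [2, 18], [3, 18]), lognormal longest-leaf lengths (median 8 cm,
σ_log 0.2), the observed biggest-leaf-rank distribution for bourse shoots,
Lorentz (or linear) area profiles, elliptical blades with Gaussian
eccentricity noise (σ 0.03), logistic spur continua with Gaussian noise on
normalized length (σ 0.05, made monotone by isotonic projection, since
cumulative length is physically nondecreasing), and a sinusoidal hourly
temperature cycle.  Single-leaf shoots are excluded by default: they carry
no profile information and make the total-area allometry degenerate
(TLA ≡ Amax).  All randomness flows from one seed through named substreams,
so the leaf, internode and temperature stages are independently
reproducible.

Two structural choices deserve emphasis:

* **Two zero-noise idealisations.**  At finite leaf number a shoot cannot
  lie exactly on the Lorentz curve *and* satisfy TLA = β·nl·Amax exactly
  (the Riemann gap above).  `profile_mode="slope-exact"` (default)
  rescales non-peak leaves so the allometry holds exactly — the slope
  estimators (β, and through them the s table) then close exactly;
  `profile_mode="shape-exact"` puts areas exactly on the curve — the
  shape estimators (x₀) and the calibration slope α then close exactly.
  Closure tests check each parameter in the mode where its estimator is
  exactly identified.  For rosettes α closes to <1 % rather than exactly:
  the model evaluates the peak at the continuous position nl·x₀ while real
  (and synthetic) leaves sit on integer ranks — the same mismatch the
  calibration stage exists to absorb.
* **Noise placement.**  The per-shoot allometry deviation (lognormal,
  CV 5 %) enters the β regression only through the response, keeping the
  through-origin slope estimators exactly unbiased; per-leaf area noise
  (lognormal, CV 10 %) is applied to non-peak leaves and clamped below the
  peak, so the biggest-leaf identity — and with it Amax and Lmax — stays
  well defined.  Unclamped peak noise would bias Amax upward (a maximum
  statistic) and β̂ downward.  α and p are embedded as a uniform
  blade-area-to-ellipse-model ratio (recorded area = α × the
  (π/4)·k·L² chain), which keeps lengths, widths and areas internally
  consistent and gives the calibration stage a real signal to recover.

Passing recovery tests on these data show that the estimators are correct
and well-conditioned under the assumed structure.  They do not show that
real orchard leaves follow a Lorentz profile, that residuals are lognormal,
or that the shipped parameter values are right for other orchards, years
or rootstocks — those are empirical questions the original measurements
answered and synthetic data cannot.

Monte-Carlo recovery at the study's sample sizes (~180 bourse shoots, 232
rosettes, 24 spurs, 50 seeds) recovers β within ±0.02, k within ±0.01, x₀
within ±0.03 and qi/si within ±0.03 on the Monte-Carlo mean, with per-seed
spreads below each band.  Unbiasedness is asserted to
max(3 Monte-Carlo s.e., 0.01): the slope estimators are exactly unbiased by
construction, while the curved estimators (k, qi, si, x₀) carry
second-order biases of order ≤ 0.006 — below the 2-decimal resolution at
which these parameters are reported.

## Numerical choices and degenerate inputs

* Root finding: Brent on a fixed bracket (monotone objective); tabulation
  of s per nl at fit time, on-demand solving beyond the table.
* Ties for the biggest leaf break toward the lowest rank.
* β ≥ 1 after fitting raises an error (the closed form has no solution;
  physically TLA ≤ nl·Amax guarantees β ≤ 1 with equality only for
  degenerate equal-leaf shoots).
* curve_fit bounds: x₀ ∈ [0, 1.5], s ∈ [10⁻³, 10], amplitude ∈ [0.2, 5]
  for the profile fit; qi ∈ [0, 1.5], si ∈ [10⁻⁴, 5] for the logistic.
* Validation is loud: non-contiguous ranks, duplicate (shoot, rank) pairs,
  non-numeric cells (row-addressed), W > L, and coverage gaps in the
  temperature record all raise typed errors.

## Known limitations

* The vegetative-shoot model is descriptive only — no calibration or
  testing stage (mirroring the available data).
* Phyllotactic angles, 3-D orientation and rendering are out of scope; the
  output is a per-leaf table (area, insertion distance).
* The grouping tests' AR-vs-FU pooling decision is a borderline 5 %-level
  call on noisy data of this size; the workflow therefore takes grouping
  as explicit configuration and reports the tests, rather than hard-wiring
  the decision.
* GDD thresholds for full development are inputs, not estimated.
* Spurs with two bourse shoots are handled as two continua sharing the
  bourse ranks.
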