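# Methods

This note documents the models implemented in `erisk`, the assumptions of
the synthetic-cohort generator, and the numerical and design choices made
where more than one reasonable option existed. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Cause-specific hazard model

Three mutually competing first-event causes are modelled on the age scale
with left truncation at the entry age:

1. **ER+ tumour** and **ER− tumour**: piecewise-constant baseline hazards
   with cutoffs at 45, 50, 55, 60, 65, 70, 75 years (first band open below,
   last open above, so any attainable age is covered), multiplied by
   `exp(β′x)`. Each covariate coefficient carries a *sharing flag*: one
   coefficient common to both causes, or one per cause. By default,
   reproductive variables (parity, number of full-term pregnancies, age at
   first FTP) and body height (per 10-cm increment) are cause-specific;
   menopausal status, age at menopause, age at menarche, HRT duration,
   breastfeeding, BMI, the BMI×menopause interaction and alcohol intake
   are shared; country/stratum coefficients are always cause-specific.
2. **Pooled competing events** (tumours of unknown ER status, other
   primary cancers, non-cancer deaths): a covariate-free Gompertz hazard
   `h(t) = exp(α + γt)`, with `γ = 0` reducing to the exponential model.

Fitting uses the Poisson equivalence of the piecewise-exponential
likelihood. Follow-up is split into age-band episodes; the episode table
is replicated once per tumour cause with cause-specific baseline strata,
and shared coefficients appear as single design columns spanning both
replicates. This *joint stacked* formulation, rather than two separate
cause fits, is what makes the sharing constraint a genuine likelihood
constraint, so the heterogeneity likelihood-ratio test
`2(ll_free − ll_constrained)` has its nominal χ² reference distribution
(df = number of coefficient copies released). Per-variable heterogeneity
tests are reported without multiplicity adjustment.

Unknown-ER tumours never contribute ER-specific events; they enter the
tumour fits as censored exposure and the Gompertz fit as events. Under
ER-status missingness at random this leaves the coefficient estimates
unbiased while deflating the ER-specific baselines by the recorded
fraction — which is also why external recalibration (below) replaces the
baselines wholesale.

### Numerics

- Newton–Raphson on the stacked Poisson likelihood with log-exposure
  offset; deterministic initialisation (zero coefficients, per-cause
  event-rate baselines); step halving enforces monotone likelihood ascent;
  convergence at gradient sup-norm ≤ 1e-8, cap of 200 iterations.
  Covariance from the inverse observed information.
- Band-cause cells without events would drive their baseline to −∞; they
  are pinned at log hazard −30 (effectively zero risk) with a warning, and
  identically-zero design columns are excluded the same way.
- The Gompertz likelihood is profiled: for fixed γ the intercept has the
  closed form `exp(α) = D/W(γ)` with
  `W(γ) = Σ (e^{γ·exit} − e^{γ·entry})/γ`; the one-dimensional profile is
  maximised on γ ∈ [−0.5, 0.5] (a generous physiological range), with the
  exponential limit used below |γ| = 1e-9. Standard errors come from a
  central-finite-difference observed information.

## Absolute risk

The 5-year absolute risk of a first ER+ (or ER−) tumour is the standard
cause-specific cumulative incidence
`P_k(a,h) = ∫_a^{a+h} h_k(t) S(a,t) dt`, with `S` the all-cause
event-free probability. The window is partitioned at the band cutoffs;
within a segment the tumour hazards are constant and the Gompertz
cumulative hazard has an exact closed form, so survival is updated
analytically. Tumour-cause increments use the constant-hazard closed form
`(h_k/H)·S·(1 − e^{−HΔ})` when the competing hazard is constant or absent,
and otherwise fixed 24-point Gauss–Legendre quadrature of the smooth
integrand against the exact within-segment survival (agreement with
adaptive quadrature is at the 1e-12 level, tested at 1e-8). The
competing-event increment is taken as the remainder of total event mass in
the segment, so cause risks and survival sum to one by construction.
Horizons are configurable; 5 years is the default, and projections start
at entry (or any landmark) age.

**External recalibration** freezes all covariate coefficients at the
source fit and re-estimates each band-cause baseline on the target cohort
by its closed-form MLE `λ = events / Σ exposure·exp(β′x)`. Source
country coefficients are dropped by default: they do not transfer to an
external population, and the recalibrated baselines absorb the target's
overall level. The competing-event Gompertz model is refitted on the
target cohort.

## Validation

- **C-statistic**: Harrell-type concordance over comparable pairs with
  follow-up truncated at the horizon — a case of the target cause at time
  t is compared with every subject at risk beyond t (including subjects
  censored exactly at t); ties in risk score one half. The underlying
  pair counting is delegated to `lifelines.utils.concordance_index` and is
  checked against exhaustive pair enumeration in the tests. Confidence
  intervals by subject-level bootstrap (200 replicates, seeded,
  percentile).
- **E/O**: expected events = Σ predicted risks; observed = crude count of
  target events within the horizon. The synthetic design guarantees at
  least 10 years of potential follow-up, so no administrative censoring
  occurs inside a 5-year window; an Aalen–Johansen-adjusted observed count
  is available as a sensitivity switch for data where it does. CI:
  `(E/O)·exp(±1.96/√O)`.
- **Decile calibration**: deciles of predicted risk with stable-order tie
  breaking; observed proportions are crude within-window event fractions.
- **Fivefold cross-validation**: seeded permutation folds (sizes differing
  by ≤1), models refitted on each 4/5, metrics on pooled out-of-fold
  predictions (pooling, rather than per-fold averaging, keeps E/O a ratio
  of totals). If a fold lacks events of either cause the partition is
  re-randomised once, then the run errors. An *eliminate-stratum* mode
  recomputes the ranking risks with country coefficients zeroed, isolating
  discrimination due to individual risk factors from between-country
  baseline differences.

## Decision curve analysis

Net benefit is `TP/n − (FP/n)·p_t/(1−p_t)` for the policy "treat if risk ≥
p_t" (closed at the threshold). The default grid runs in 5e-4 steps from
5e-4 to the maximal risk estimate. The applicability area integrates
`NB_model − max(NB_all, 0)` by the trapezoidal rule, decomposed into its
negative and positive parts; the total is their sum. The threshold
relation `p_t·B = (1−p_t)·H` gives `B/H = (1−p_t)/p_t`; quoted ratios are
conventionally rounded to the nearest multiple of 5 (`rounded=True`),
under which thresholds of 0.55%, 2.5% and 4% map to 180, 40 and 25. The
strict algebra `(1−p_t)/p_t` and the rounding convention are both exposed
because quoted ratios in the applied literature are indistinguishable from
`1/p_t` at these magnitudes.

## Synthetic cohort generator

The generator emulates a multi-centre European cohort of women aged 40–70
at recruitment. Defaults (all overridable through `CovariateConfig` /
`TrueModel`):

- entry age uniform on [40, 70); 51% postmenopausal at entry; height
  normal(162 cm, 6.5 cm); categorical risk factors from configured
  marginals with the structural dependencies of the coding (age at
  menopause only when postmenopausal; parity detail and breastfeeding only
  when parous; the BMI×menopause code 0–3 derived from its parents);
  four country strata with no baseline differences unless configured.
- ground-truth coefficients: the published ER-specific hazard-ratio table
  (e.g. postmenopausal vs premenopausal 0.66 shared; height per 10 cm 1.19
  for ER+ vs 1.06 for ER−).
- baseline tumour hazards rising with age, at levels giving crude rates of
  roughly 1.7 (ER+) and 0.4 (ER−) per 1000 person-years; Gompertz
  competing hazard α = −10.3, γ = 0.09 (≈5.7/1000 at age 57, doubling
  every ~8 years). Together these reproduce the overall event burden of a
  large prospective cohort at realistic follow-up.
- 25% of simulated tumours relabelled to unknown ER status; administrative
  censoring after uniform(10, 18) years of follow-up, truncated at age 80
  (mean realised follow-up ≈ 13 years).

Event times are sampled exactly: one latent time per cause channel by
analytic inverse-CDF inversion (band-by-band for the piecewise tumour
hazard, closed form for the Gompertz), minimum taken, tumour subtype
assigned proportionally to the cause hazards in the event band. Because
cause channels are independent at the intensity level, this latent-minimum
scheme is distributionally identical to inverting the total hazard and
requires no root finding.

**What the generator does not emulate** — and hence what passing tests do
not establish about real cohorts: menopausal status is drawn independently
of entry age (no age confounding, which keeps recovery tests clean but is
epidemiologically idealised); covariates are mutually independent given
the structural dependencies; no calendar-time or cohort effects; no
family history or breast-biopsy variables; hazards are exactly
proportional and exactly piecewise-constant, so model misspecification is
absent by construction. Validation metrics on these cohorts demonstrate
correctness of the machinery, not expected real-data performance.

## Multiple imputation

Chained equations with variable-by-variable conditional draws: parents
(menopausal status, parity) imputed before their dependants; multinomial
logistic models for categoricals, normal-linear for continuous variables
with draws truncated to the observed range (bounded epidemiological
quantities); the tumour-event indicator and log follow-up time enter every
conditional model. Tables start from a random hot-deck fill and cycle 10
sweeps by default; imputation j uses seed `seed + j`. Structural
non-applicability is never imputed, and applicability is re-evaluated
whenever a parent changes during a sweep. Conditional-model failures fall
back to marginal draws with a warning. Parameter uncertainty of the
conditional models is not redrawn per imputation (improper MI in Rubin's
terminology); for the moderate missingness fractions exercised here the
effect on pooled inference is small, and Rubin's rules
(`T = W + (1 + 1/m)B`, Barnard–Rubin degrees of freedom) are applied
downstream unchanged.

## Problem sizes used in the checks

Deterministic algebra and small fixtures run instantly; parameter-recovery
checks use one cohort of n = 200,000 (estimates agree with the generating
values within 3 SE); the LRT size check uses 500 replicates of n = 20,000
under a reduced two-covariate model, which keeps the whole simulation at a
few minutes while leaving ~70 ER− events per replicate — enough for the
χ² approximation to hold at the 0.05 ± 0.03 level tested; calibration and
external-validation checks use cohorts of 40,000–60,000.

## Known limitations

- The C-statistic's censoring handling follows the comparable-pairs
  definition above; inverse-probability-of-censoring weighting is not
  implemented.
- Confidence bands for net-benefit curves are out of scope, as are
  time-varying covariates, frailty terms and spline baselines.
- The Gompertz competing model carries no covariates; competing-event risk
  varies only with age.
- `PersonTimeTable` episode splitting assigns an event occurring exactly
  at a band cutoff to the band the subject was about to enter only if
  exposure there is positive; with continuous ages this is measure-zero.
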