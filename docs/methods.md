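# Methods

## The candidate STAR index

STAR (Sjögren's Tool for Assessing Response) is a composite responder
index for primary Sjögren's syndrome (pSS) trials.  Five domains are
scored from two visits (baseline, follow-up):

| Domain | Weight | Instruments | Response rule |
|---|---|---|---|
| Systemic activity | 3 | clinESSDAI | decrease ≥ 3 points |
| Patient symptoms | 3 | ESSPRI (0–10) | decrease ≥ 1 point or ≥ 15% |
| Lachrymal function | 1 | Schirmer (mm) / OSS (0–12) | Schirmer: abnormal (< 5 mm) baseline → gain ≥ 5 mm, normal baseline → stay normal.  OSS: abnormal (≥ 3) baseline → drop ≥ 2, normal baseline → stay < 3 |
| Salivary function | 1 | UWSF (mL/min) / Hocevar US (0–48) | UWSF: baseline > 0 → gain ≥ 25%, baseline 0 → any gain.  Ultrasound: total score drop ≥ 25% |
| Biology | 1 | IgG (g/L) / RF (IU/mL) | IgG drop ≥ 10% or RF drop ≥ 25% |

A patient is a responder at **≥ 5 points**.  Because the three minor
domains sum to only 3, a responder must improve in at least one major
domain — verified in the tests by exhaustive enumeration of the 2⁵
response patterns.

Conventions where the published rules are silent:

* **Instrument alternatives ("or")** — a domain responds if *any*
  instrument with both visits available meets its rule.
* **Missing data** — a domain with no usable instrument pair is
  *undetermined* and earns 0 points (conservative, biases against
  response); the per-patient count of undetermined domains is surfaced.
* **Zero ultrasound baseline** — scored "no" (a zero total cannot
  decrease by 25%); the flow instrument has its own explicit zero rule.
* **Maintenance counts** — a glandular instrument that is normal at
  baseline responds by *staying* normal.  This inflates glandular
  response rates in mild patients in both arms and is deliberate: it is
  how the rules are written.
* **Inclusive thresholds at double precision** — "≥ 25%" must hold for
  values exact in decimal but not in binary: `(0.25 − 0.20)/0.20`
  evaluates *below* 0.25 in doubles.  All threshold comparisons therefore
  allow a 1 × 10⁻⁹ absolute-plus-relative tolerance.  This changes no
  classification except at exact decimal boundaries, where it enforces
  the printed rule.

## Endpoint design families (option space)

`OptionSpec` parameterises seven composite designs: SRI-like (one
improved major domain and no worsening elsewhere, with one or two
eligible majors), counting designs (≥ 3 of 5 improved domains, with or
without a mandatory major — the latter is the CRESS-like preset), the
weighted point sum (3/3/1/1/1) either dichotomised at a threshold from 4
to 9 or compared between arms as a continuous 0–9 score, and an ACR-like
family applying a single uniform percent-improvement cutoff (10–70%,
default grid step 10) to every instrument.

No consensual published definition of *worsening* exists; the default
worsening rule is the mirror image of each improvement rule (e.g.
clinESSDAI increase ≥ 3, normal-to-abnormal transitions for the ocular
instruments), overridable per domain.  A domain worsens if any available
instrument worsens.

## Between-arm statistics

* **Cohen's d** uses the pooled-SD two-sample form.  Its CI comes from
  the noncentrality-parameter method: find the noncentralities placing
  the observed t statistic at the α/2 and 1 − α/2 tails of the
  noncentral-t distribution (Brent root-finding, tolerance 10⁻⁸, bracket
  ±(|t| + 10) widened as needed; deep-tail CDF underflow is mapped to its
  limit), then rescale by √(1/n₁ + 1/n₂).  Effect sizes are classed by
  magnitude: |d| > 0.8 large, 0.5–0.8 moderate, < 0.5 small; the
  ambiguous boundary 0.8 is classed moderate (closed upper bound).
* **Hedges' g** applies J = 1 − 3/(4·df − 1).
* **C-index** is the Mann–Whitney concordance with ties credited 0.5,
  computed by exact pair counting up to 10⁶ pairs and by the identical
  midrank formula above that.  On a binary responder indicator it equals
  the AUC of responder status against arm.  Both change scores and final
  values can be analysed.

## Meta-analysis

Binary options pool as odds ratios: Mantel–Haenszel on the raw counts for
the fixed-effect estimate (Robins–Breslow–Greenland CI, via statsmodels),
and inverse-variance random effects on per-study log-ORs with weights
1/(vᵢ + τ²).  A 0.5 continuity correction is added to all four cells of a
study *only* when it contains a zero cell.  τ² is the Paule–Mandel
estimator (iterative moment solution of Σwᵢ(yᵢ − μ̂)² = k − 1, truncated
at zero, tolerance 10⁻¹⁰); its CI is the Q-profile interval (τ² values
where the generalised Q equals the χ²ₖ₋₁ quantiles, truncated at zero;
the τ interval is the square root).  Continuous options pool Hedges' g
with the Hedges–Olkin large-sample variance
(n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂−3.94)), matching the statsmodels
convention used as a cross-check.  Pooled CIs use the normal
approximation (no Knapp–Hartung; the paired trials analyses do not use
one).  With a single study τ² is fixed at 0 and flagged not estimable.
Null references: OR = 1, SMD = 0.

## Virtual-twins subgroup discovery

Stage 1 fits a bagged-tree classifier (default 500 bags, leaf ≥ 5) on
baseline covariates plus the arm indicator and predicts each patient's
response probability with the arm toggled; predictions are **cross-
fitted** (stratified K-fold, default K = 10) so each patient is predicted
by a model that never saw them.  Stage 2 grows a regression tree on the
estimated individual effect z = p₁ − p₀ with a minimum leaf size of 60
(the screening power floor), pruned by cost-complexity with a
cross-validated α (1-SE rule), so that a constant effect yields a
root-only tree.

Leaf subgroups are reported with their raw relative risk (RR) of
response, treatment vs placebo, and an **optimism-corrected RR** built
from three components:

1. continuity-corrected leaf log-RRs (0.5 added to responder counts);
2. empirical-Bayes shrinkage toward the whole-population log-RR, with
   between-leaf variance τ² admitted only when a χ²-homogeneity pretest
   rejects at α = 0.01 (DerSimonian–Laird moment estimate thereafter) —
   leaves chosen where the estimated effect is largest are exactly the
   leaves whose RR is inflated by selection, and under a true null the
   pretest keeps every leaf at the population RR;
3. subtraction of a cross-validated procedure-level optimism: on each of
   3 × 5 train/test splits the tree is rediscovered on the training part,
   its highest-RR leaf identified, and the train-minus-test gap of that
   leaf's log-RR recorded; the mean gap (floored at 0) is removed from
   upward deviations.

A subgroup is *selected* when its corrected RR is at least 1.5× the
whole-population RR ("notably higher", quantified as a configurable
multiplier) and it holds ≥ 60 patients.  When the population RR is
undefined (no placebo responders) the ratio cannot be assessed and the
subgroup is left unselected, flagged.  This calibration makes the
screening specific: on simulated null trials (n = 400) no subgroup is
selected in ≈97% of replications, while a planted subgroup with RR ≈ 3.5
against an overall ≈1.6 is both split on (first split recovers the
planted covariate essentially always) and selected.

## Synthetic pSS trial generator

Patient-level data from the historical trials are not available, so the
evaluation machinery runs on simulated trials emulating their shapes:
nine trials of sizes 80, 52, 120, 29, 27, 32, 133, 120, 110, labelled
in_between, negative, negative, positive, positive, positive,
in_between, in_between, negative — six trials where an effect is
expected and three where none is.

**Baselines.**  A single latent Gaussian severity factor (loading
ρ = 0.4) drives all instruments through a Gaussian copula — severer
patients score worse everywhere.  Marginals are range-respecting
defaults, chosen once for clinical plausibility and not calibrated to
any real dataset: clinESSDAI ~ negative binomial (mean 10, capped at
40); ESSPRI ~ truncated normal (6 ± 2 on [0, 10]); Schirmer ~ 10%
zero-inflated gamma (mean ≈ 6 mm); OSS ~ binomial(12, 0.35); UWSF ~ 15%
zero-inflated gamma (mean ≈ 0.18 mL/min); Hocevar ~ truncated normal
(18 ± 8 on [0, 48]); IgG ~ lognormal (median 14 g/L); RF ~ 30%
zero-inflated lognormal (median 40 IU/mL).

**Follow-up.**  baseline + arm-dependent mean change + Gaussian noise;
additive in instrument units for the point-scored instruments
(clinESSDAI, ESSPRI, Schirmer, OSS), relative (fractional) for the
flow/ultrasound/serology instruments, then clipped to the instrument
range and rounded to its granularity (ESSPRI 0.1, UWSF 0.01, IgG 0.1,
integers elsewhere).  The *positive* profile improves all domains
(e.g. clinESSDAI −3.5 vs −1.0 under placebo); the *in-between* profile
improves mainly the glandular/serological measures with weak major-
domain effects — the pattern of trials that missed their primary
endpoint but showed secondary-endpoint signal; the *negative* profile
sets treatment parameters exactly equal to placebo, making the null true
by construction (enforced by a validation invariant).

**Missingness** is instrument-level per patient (both visits or
neither), defaulting high for the instruments absent from most
historical trials (ultrasound 50%, RF 30%, OSS 25%) and low elsewhere.
**Seeding**: one master seed; per-trial child streams via
`numpy.random.SeedSequence.spawn`, so the suite is reproducible and
trials are independent.

What the generator does **not** emulate: real covariance structure
between instruments (the single-factor copula is a stylised stand-in),
drug mechanisms, informative dropout, visit-schedule irregularities.
Passing calibration tests therefore shows internal consistency of the
machinery under controlled conditions, not performance on real pSS data.

## Evaluation pipeline

Every option × trial cell yields responder counts (binary) or arm
summaries of the 0–9 point score (continuous) plus a C-index.  Patients
whose classification is ambiguous under missing data — resolving their
undetermined domains optimistically versus pessimistically flips the
flag — are excluded from that option's 2×2 with the count reported.
Positive and in-between trials pool together; negative trials pool
separately.  Options are ranked by |pooled effect|_positive −
λ·|pooled effect|_negative on the analysis scale (λ = 1 by default;
λ = 0 degenerates to pure sensitivity).  The ranking is a quantitative
screen only; the historical index selection additionally weighed
clinical relevance by expert consensus, which no score reproduces.

## Problem sizes used by the test suite

Exhaustive enumerations run over all 32 domain patterns.  The coverage
check of the noncentral-t interval uses 2,000 two-arm draws at n = 30
per arm.  Virtual-twins calibration uses 100 replications each for
recovery and null specificity at n = 400 with reduced learner settings
(50 bags, 5 cross-fit folds) — hyperparameters the method leaves free;
the conclusions are unchanged at the heavier defaults.  Pipeline
calibration uses 50 replications of the full nine-trial suite.

## Known limitations

* The simulator's marginals and effect profiles are stylised defaults;
  absolute responder rates should not be read as pSS estimates.
* The Delphi/consensus layers of the original development (option
  voting, trial classification, final selection) are inputs here, not
  reproduced processes.
* The virtual-twins optimism correction is calibrated for binary
  responses with two-arm parallel designs; censored or repeated-measures
  outcomes are out of scope.
* Subgroup rules are axis-aligned conjunctions (tree branches);
  interactions requiring oblique splits will be approximated or missed.
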