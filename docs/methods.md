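# Methods

This note documents the modeling choices behind `usvtwin`: what each stage
assumes, which parameters matter, and what the synthetic study design can
and cannot show.

## 1. Synthetic source cohort (`usvtwin.source`)

No patient-level USVT registry is publicly available, so the pipeline
starts from an emulator calibrated to published summary statistics of a
real-world cohort of 90 patients (65 VKA / 25 DOAC).

**Sampling model.** Treatment arm is Bernoulli (P(VKA) = 65/90). Within
arm, every covariate is drawn independently from its configured marginal:

- *Site*: VKA (45/65 SVT, 20/65 UEDVT, 0 CVT), DOAC (10/25, 13/25, 2/25).
- *Comorbidities, thrombophilia, antiplatelet use, sex*: arm-conditional
  Bernoulli at the published per-arm counts (e.g. active cancer 25/65 VKA
  vs 4/25 DOAC).
- *Age*: normal(67.5, 17.7²) truncated to [18, 100] by clipping.
- *Labs and follow-up*: log-normal per arm, with μ = log(median) and
  σ = log(q3/q1)/(2·z₀.₇₅) matched to the printed medians/IQRs
  (positive-support families consistent with the published summaries).
- *TTR* (VKA only): Beta on [0, 100], moment-matched to median 60.9% and
  IQR 51.4–70.8 (treating the printed median/IQR as location/scale of a
  roughly symmetric distribution).
- *Outcomes*: arm-conditional Bernoulli — VKA: complete recanalization
  0.36 (among imaged), recurrence 0.077, major bleeding 0.108, death
  0.60; DOAC: 0.40, 0.08, 0.08, 0.20. Follow-up imaging availability is
  itself arm-conditional (25/65 VKA, 15/25 DOAC imaged), and
  recanalization is missing for unimaged records.

Only arm-conditional margins are encoded because the published summaries
constrain nothing beyond them; higher-order dependence is a config
surface, not an invented default. The emulated summaries contain one
internal inconsistency (per-arm mortality overall vs in the non-cancer
stratum cannot be reconciled with the cancer counts); the emulator
reproduces marginal counts per variable and makes no claim about the
cancer×death joint cell.

**INR/TTR.** The Rosendaal method interpolates linearly between
consecutive INR measurements and reports the percentage of elapsed time
with interpolated INR in [2.0, 3.0]; segment contributions are computed
analytically from the linear crossing points. The INR simulator is a
mean-reverting AR(1) walk around 2.5 (ρ = 0.7) whose stationary SD is set
so a single draw is in-range with the target probability; linear
interpolation biases realized TTR slightly upward (opposite-side
excursions cross the range), which stays within the simulator's ±5
contract at a 60% target.

## 2. Digital-twin generator (`usvtwin.gan`)

**Architecture.** One generator head per non-conditioning variable (a
small dense network, widths 64–64), plus a single discriminator
(64–64) on the full encoded record. Variables are generated in
topological order of a clinical dependency DAG; a DAG node's head
receives latent noise plus *only its parents'* values (conditioned or
previously generated), other variables' heads receive the conditioning
block. The default DAG has the five key covariates (site, treatment, age,
sex, cancer) as roots and the three outcomes as terminal nodes; outcomes
are never conditioning variables.

**Encodings.** Categorical variables are one-hot; binary flags 0/1;
continuous variables z-scored. Missingness is modeled explicitly where it
is informative: imaging availability is an auxiliary binary variable, and
recanalization is decoded only for imaged records. TTR and DOAC-agent
consistency with treatment arm is enforced at decode time.

**Training.** Alternating single-step Adam updates (lr 1e-3, β₁ = 0.5) on
a binary cross-entropy objective, batch 32, default 2000 epochs. Three
stabilizers matter at n ≈ 90 and are worth naming:

1. *Straight-through concrete sampling* — the discriminator sees hard 0/1
   samples (gradients flow through the soft sigmoid/softmax at
   temperature 0.66), so it cannot separate real from fake by relaxation
   softness;
2. *Instance noise* — Gaussian noise (sd 0.4) on every discriminator
   input, the key regularizer preventing the discriminator from
   memorizing the 90 training rows;
3. *One-sided label smoothing* (real target 0.9).

Gradients into generated parents used as context by later heads are
stopped; each head learns from the discriminator's direct view of its own
output.

**Convergence** is declared when, over the trailing window (default 100
epochs), the first- and second-half means of each loss series differ by
at most 5% relative. Because adversarial losses hover near equilibrium
for most of training, this criterion only gates optional early stopping;
fidelity metrics are the post-hoc arbiter of twin quality, and
non-convergence is flagged on the model rather than raised.

**1:1 generation** reuses the training rows' conditioning values, so the
conditioned margins (and the joint distribution of the five key
covariates) match the source exactly; requesting a different n resamples
conditioning rows with replacement. Generated continuous values are
clipped to the training range ± 5% slack (domain closure). Replica *i*
of a reproducibility set uses seed `seed_base + i` — distinct but
controlled.

## 3. Fidelity metrics (`usvtwin.fidelity`)

ASMD uses the pooled-variance (Cohen's-d-style) denominator — continuous:
|m₁−m₂|/√((v₁+v₂)/2) with sample variances; binary: Bernoulli variances;
multi-level categorical: the mean of per-level dummy ASMDs (chosen over a
Mahalanobis variant for interpretability). MASMD is the mean of
per-variable ASMDs with the sample SD (ddof = 1). Thresholds follow the
balance-diagnostics convention: < 0.10 target, ≤ 0.20 acceptable.

MMD² is the unbiased Gaussian-kernel estimator (diagonal terms omitted,
hence slightly negative values are possible under the null) with the
median-heuristic bandwidth on the pooled standardized continuous block;
significance uses a 200-permutation null with the bandwidth held fixed.
KS is applied to continuous marginals only; categorical marginals are
compared by total-variation distance because KS is invalid under heavy
ties. Spearman structure similarity integer-encodes mixed variables
(site as the ordinal SVT = 0, UEDVT = 1, CVT = 2 — documented and
configurable) and reports the fraction of off-diagonal pairs with
|Δρ| < 0.1, excluding constant variables.

## 4. Conditioning (`usvtwin.matching`)

Propensity scores come from a maximum-likelihood logistic model of DOAC
assignment on age, sex, site (two dummies vs the modal SVT category) and
active cancer; constant design columns are dropped (coefficient 0), and
separation or non-convergence falls back to a weakly L2-penalized fit,
flagged. Matching is greedy 1:1 nearest-neighbour without replacement on
the logit-score scale, smaller arm iterated in a seeded random order,
caliper 0.2 × SD of the logit scores (∞ disables it). Balance is the
per-variable ASMD between matched arms against the same 0.10/0.20
thresholds. Matching is performed within the twin cohort, so the
conditioned cohort is fully synthetic.

## 5. Outcome models (`usvtwin.models`)

Per-endpoint logistic regressions with default predictors treatment,
site, active cancer (age, sex and a binary good-VKA-control flag are
toggles; the control flag is TTR ≥ 70%, threshold configurable, and is
what the perfect-control scenario switches on). Recanalization is coded
complete = 1 vs not-complete = 0, fitted on imaged records and predicted
for all records — extrapolation under an assumed ignorable missingness
given the predictors, which is a documented assumption, not a tested one.

Site dummies carry a ridge penalty (default strength 1.0) because the
CVT stratum is tiny (two patients at source scale) and cannot support
unpenalized estimates; with the penalty at 0 the fit is exact ML and
reproduces the closed-form saturated two-group logit. Fits use
Newton–Raphson with a selective penalty vector; Wald CIs come from the
inverse (penalized) observed information.

Marginal risks are counterfactually standardized (every record scored
under both arms); a treatment-only model therefore reproduces the raw
arm rates exactly. CIs are percentile bootstrap over records with model
refitting (1000 resamples by default; degenerate resamples are skipped).
The bootstrap-percentile choice is a labeled convention — profile or
delta-method intervals would be equally defensible.

## 6. Monte Carlo engine (`usvtwin.mc`)

Layer 1 resamples a case-mix of M profiles *within strata of the
perturbed variable* (exact stratum counts at the target shares), so the
target marginal is hit while within-stratum joint structure is preserved.
Scenario definitions: 70% DOAC; active-cancer prevalence × 1.5 (34.4% →
51.6% at the published baseline); CVT 40%; and perfect VKA control, which
is a deterministic TTR := 100 edit of VKA rows rather than resampling. A
required-but-empty stratum raises a scenario-infeasible error naming the
stratum. An alternative simple weighted-resampling scheme exists for
sensitivity analysis.

Layer 2 draws each simulated outcome from Bernoulli(model probability)
and averages within arm. **M defaults to 4000**: with roughly balanced
arms this puts the empirical 95% CI half-widths at ~1–2 percentage
points, the scale of the published simulation table, whereas M = 90 would
give CIs an order of magnitude wider. R defaults to 500 iterations; both
case-mix and outcome draws are refreshed every iteration. The seed ladder
is master → (master, scenario index) → (master, scenario, iteration) via
`numpy.random.SeedSequence`, so any iteration is individually
reproducible.

Diagnostics per scenario × endpoint × arm: mean rate, empirical
2.5/97.5-percentile CI, MCSE (absolute and as % of the mean; flag at
< 5%), CV (flag at < 10%). Directionality is the fraction of iterations
whose DOAC−VKA difference keeps the reference sign; exact zeros count as
non-preserving (conservative). The reference signs used by the test suite
are the source generator's configured truth (+ recanalization,
+ recurrence, − bleeding), which coincide with the published real-cohort
directions; the pipeline artifact also reports directionality against
the realized signs of the sampled source cohort, which can differ at
n = 90 for near-null effects.

## 7. Problem sizes and determinism

Default study conditions mirror the emulated cohort: n = 90 source
records, 1:1 twins, ten replicas for reproducibility assessment, R = 500,
M = 4000. The test suite runs reduced orchestration smoke tests
(shorter training, fewer iterations) alongside full-scale acceptance
checks. All randomness flows from explicit seeds; rerunning any stage
with the same config and seed is byte-identical.

## 8. What passing tests do and do not show

The synthetic source cohort reproduces *arm-conditional marginals* of a
real registry. It does not carry real patients' higher-order dependence
(beyond site/cancer arm composition), longitudinal structure, informative
imaging selection, or cause-of-death detail — so twin fidelity and
downstream effect estimates demonstrate that the pipeline's machinery is
correct and calibrated, not that the clinical conclusions transfer.

Two intrinsic small-sample limits are worth stating plainly. First, the
conditioned matched cohort is small (~23 pairs when matching 25
DOAC-equivalent twins under the default caliper); logistic treatment
effects fitted on ~46 rows with 2–4 events per endpoint — and on ~20
imaged rows for recanalization — carry sampling SDs of several (for the
rare endpoints) to ~20 (recanalization) percentage points. Point
estimates of the between-arm differences at this scale are therefore
noise-dominated, and a single pipeline realization can miss the
generating signs for the near-null recurrence (+0.3 pp true difference)
and bleeding contrasts. Second, directionality fractions are computed
*given* the fitted models, so they quantify Monte Carlo stability around
the fitted effect, not the sampling uncertainty of the effect itself.
Fixing the per-arm probabilities at known values (the engine-validation
configuration) removes the first limit and is the appropriate way to
check the simulation machinery in isolation.

Other known limitations: no time-to-event or competing-risk structure
(mortality is descriptive only and 60% in the VKA arm, so
treatment-effect estimates for non-fatal endpoints ignore substantial
informative censoring in the emulated reality); no differential-privacy
guarantees for the generator; the DAG is a fixed expert-style default,
not learned from data.
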