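# Methods

## Pharmacokinetic models

Both drugs are described by one-compartment disposition models with
transit-compartment absorption. Drug passes through a chain of *n*
hypothetical transit compartments at rate k_tr = (n+1)/MTT, producing the
gamma-shaped input rate

    r(t) = F · D · k_tr · (k_tr t)^n · e^(−k_tr t) / Γ(n+1),

then a depot empties into the central compartment at first-order rate
k_a. Γ(n+1) replaces n! so non-integer transit numbers are accepted.
Elimination is first-order for pyrazinamide (CL/V) and Michaelis–Menten
for rifampicin (v_max·C/(k_m + C)), whose v_max doubles once
autoinduction is complete. The autoinduction *time course* is not
modelled: thresholds are simulated at full induction (the steady-state
condition of the analysis), and the synthetic-data generator switches
v_max from pre-induction to induced as a step at day 14. The pre-/post-
induction capacity ratio (2.0) is retained as a configuration invariant.

Disposition parameters scale allometrically with fat-free mass: power
0.75 for clearance-type parameters (CL, v_max), 1.0 for volume. Fat-free
mass uses the BMI-parameterised formula with constants (9270, 6680, 216)
for men and (9270, 8780, 244) for women. Between-subject variability is
log-normal (multiplicative exp(η), η ~ N(0, ω²)) on clearance/v_max,
bioavailability, k_a and MTT.

### Default parameter values

The analysis models in the source literature are not reprinted with
their numeric estimates, so the defaults in
`src/tpt_adherence/data/drug_models.yaml` are implementer-chosen
representative values for adults with TB–HIV co-infection, constrained
by the pharmacology the pipeline must reproduce:

| parameter | pyrazinamide | rifampicin | notes |
|---|---|---|---|
| CL / v_max (pre-induction) | 3.4 L/h | 60 mg/h | at reference FFM (42 / 40 kg) |
| k_m | — | 8 mg/L | |
| V | 30 L | 50 L | |
| MTT, n, k_a | 0.5 h, 5, 3.0 /h | 0.7 h, 7, 1.2 /h | |
| induction fold | 1 | 2 | induced = 2 × pre-induction |
| ω² (CL/v_max, F, k_a, MTT) | 0.045, 0.04, 0.3, 0.1 | 0.05, 0.04, 0.4, 0.2 | log-scale variances |

Two constraints deserve comment. First, the pyrazinamide defaults imply
a half-life of ≈ 6.1 h at the reference size. Intro-level summaries of
pyrazinamide often quote ~9 h; with a 9 h half-life, however, the 48 h
post-dose 2.5th-percentile concentration sits *above* the 0.203 mg/L
LLOQ for typical adults, which contradicts the well-established
observation (and this pipeline's informativeness rule) that pyrazinamide
is expected to be unquantifiable by 48 h. A ~6 h half-life — consistent
with population estimates in TB–HIV cohorts — reproduces the correct
informativeness pattern and is used. Second, the rifampicin BSV
variances on F and v_max are kept moderate because a Michaelis–Menten
drug whose average intake rate F·D/τ exceeds v_max has no steady state;
the steady-state routine checks this explicitly and raises a diagnostic
rather than iterating forever.

### Numerics

*Linear model.* The transit→depot→central cascade has a closed-form
single-dose solution in terms of the regularised lower incomplete gamma
function P:

    A(t) = F·D·k_a/(k_a−k) · [g(k,t) − g(k_a,t)],
    g(λ,t) = (k_tr/(k_tr−λ))^{n+1} · e^{−λt} · P(n+1, (k_tr−λ)t),

valid for k_tr > λ. This is exact and vectorises over Monte-Carlo draws,
which is what makes 5·10⁶-profile calibration experiments cheap. Steady
state is obtained by superposing single-dose profiles over preceding
doses until the added term falls below 10⁻⁶ of the running sum. The
representation of the k_a-term requires k_tr > k_a; rare joint BSV tail
draws violate this, and there the term is dropped only where it is
provably below machine precision (k_a·t > 45) — otherwise an error is
raised rather than returning an approximation. An independent multi-dose
LSODA integration serves as the test oracle (agreement to 0.1%).

*Saturable model.* Integrated numerically with an adaptive 8th-order
explicit Runge–Kutta method (DOP853) at rtol 10⁻⁸, atol 10⁻¹⁰. The
system is only mildly stiff at the shipped parameters (k_tr ≈ 11/h vs an
effective elimination constant ≈ 0.3/h), and an explicit method lets the
whole Monte-Carlo batch (10⁴–10⁵ individuals, two states each) integrate
as one vectorised system; implicit stiff solvers would form dense
Jacobians in the batch dimension. Dosing intervals are repeated until
each individual's trough changes by < 10⁻³ (relative) between intervals;
converged individuals are frozen so a few slowly accumulating draws
(intake close to capacity) do not hold the batch. Mass balance of the
integration is verified by quadrature to 10⁻⁶ relative.

*Degenerate inputs.* Zero dose yields zero concentration; zero BSV
collapses the simulated distribution to the deterministic profile (both
are tested); k_a = k is handled by a relative 10⁻⁸ perturbation of the
removable singularity.

## Personalised thresholds and informativeness

For each participant × drug × visit, n_sim = 500 virtual individuals
share the participant's fat-free mass and dose; their steady-state
concentrations at 24 h and 48 h after the last dose form the reference
distribution, and its 2.5th and 5th percentiles (linear interpolation
between order statistics, rank 1 + (p/100)(n−1)) are the thresholds.
Residual assay error is *excluded* from threshold simulation by default
— the thresholds describe the distribution of true model concentrations
under full adherence — with a flag to include it for sensitivity
analysis. Percentile noise at n_sim = 500 has a coefficient of variation
of ≈ 8% for the 2.5th percentile (tested < 15% across seeds).

A threshold below the assay LLOQ is flagged uninformative and refused at
classification time: when even full adherence is expected to measure
BLQ, a BLQ result carries no adherence information. Under the default
configuration this removes rifampicin entirely (24 h and 48 h) and
pyrazinamide at 48 h, leaving pyrazinamide at 24 h — the 48 h cells are
still computed and reported, they simply never reach the regression.

Calibration: because each observation and its threshold come from the
same population model, the probability that a fully adherent
participant's concentration falls below their own interpolated 2.5th
percentile of 500 draws is ≈ 13.475/501 ≈ 2.7%, slightly above 2.5% —
the acceptance experiment measures it at ≈ 2.5–2.9% over 10,000
participants.

Random streams are split per (master seed, participant, drug, week), so
any single participant's thresholds are reproducible in isolation and
independent of processing order.

## Classification rules

Method 1 (LLOQ): non-adherent iff the measurement is ≤ LLOQ (the
boundary is inclusive; BLQ-coded records count as below). Method 2
(personalised): non-adherent iff strictly below the 2.5th- or
5th-percentile threshold; equality is `not-confirmed`. The asymmetric
language is deliberate: a value above a threshold cannot confirm
adherence, because a dose taken the same morning produces high
concentrations regardless of earlier behaviour. On informative cells
method 2 dominates method 1 (any threshold ≥ LLOQ flags everything the
LLOQ rule flags). Missing samples are skipped, never imputed, so
denominators shrink. A sensitivity filter drops week-8 records whose
actual visit day exceeded 56 days (those participants may have completed
pyrazinamide before sampling).

## Matched case–control inference

The conditional likelihood of a 1:m matched set is the softmax
probability that the case is the member with the observed covariates;
conditioning eliminates every set-level term, which is exactly what
controls for the matching variables. The fit is Newton–Raphson from
β = 0 with step halving (score tolerance 10⁻⁸, step tolerance 10⁻¹⁰);
standard errors come from the inverse observed information, giving Wald
odds ratios, 95% CIs exp(β ± 1.96·SE) and two-sided normal p-values at
α = 0.05. Estimates drifting past |β| > 15 are flagged as complete or
quasi-separation and reported without estimates. The Newton fit is
tested against dense grid search and bounded scalar maximisation of the
same likelihood, against the closed-form discordant-pair OR (n10/n01)
for 1:1 designs, and against an independent library implementation.

Weight and sex enter as adjustment covariates, mirroring the analysis
design, even though they are also matching variables. With exact sex
matching the sex coefficient is strictly non-identified (it never varies
within a set) and is dropped with a note; weight varies within the ±5 kg
caliper and is retained, though weakly identified.

**Wald vs score p-values.** At the design size (28 sets) with a modest
exposure prevalence (10–20% non-adherence), the Wald test is measurably
conservative: across 1000 null replicates of the full pipeline its
type-I error was ≈ 3%, driven by the discreteness of the exposed counts
and the exclusion of separated fits. The results table therefore carries
two p-values: `p` (Wald, matching the conventional OR + CI + p reporting
format) and `p_score`, a profile score test of the non-adherence term at
zero — nuisance coefficients maximised under the null, the squared
efficient score referred to χ²₁. The score test is defined under
separation and measured ≈ 4.4% type-I over 3000 null replicates; it is
the pipeline's test of record for the week-level null hypothesis, and
the calibration tests check it.

## Synthetic-data generator

The generator is a design replica, not a fit to any dataset. Covariates
anchor on the published cohort characteristics: weight log-normal with
median 56 kg truncated to 30–81 kg; heights normal by sex (1.65/1.63 m,
SD 0.06, truncated 1.48–1.89 m); 50% male. Controls are drawn from the
population weight distribution conditioned on their case's ±5 kg caliper
window and share the case's sex, so matching is generative rather than
algorithmic. Doses follow a 4-band fixed-dose-combination table
([30,38) → 2, [38,55) → 3, [55,71) → 4, [71,∞) → 5 tablets; 150 mg
rifampicin + 400 mg pyrazinamide per tablet); the band table and caliper
are configuration, as neither is published.

Dose-taking is i.i.d. Bernoulli per day (a persistent Markov variant
with the same stationary mean sits behind `markov_rho`). Defaults are
0.70 (cases) vs 0.82 (controls), chosen once so the synthetic
pyrazinamide non-adherence frequencies land near the published ~20% vs
~14%; the validation scenarios override them (0.6 vs 0.9 for power,
equal values for null calibration). Visits fall on days 14/28/56, with a
29/140 fraction of week-8 visits displaced to days 57–64 and ≈ 6% of
case samples missing, mirroring the published accounting. Samples are
taken just *before* the visit-day dose at 24·day + ε hours (ε truncated
normal, SD 2 h), so the time since the last taken dose is ≈ 24 h plus
24 h per consecutively missed day. Observed values add 20% proportional
and 0.02 mg/L additive residual error and are masked below the LLOQ.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: unrecorded same-day dosing before the
blood draw (the dominant real-world confounder; it is why the real
rifampicin BLQ fraction is ~45–52% while the generator's is ~55–60%),
dose-timing drift other than Gaussian jitter, pharmacokinetic model
misspecification, and any dependence of adherence on covariates or time
(beyond the optional Markov streakiness). Operating characteristics
(type-I error, coverage, power) are therefore statements about the
pipeline under its own model, not about the field performance of the
method.

## Problem sizes used in validation

Threshold calibration uses 10,000 virtual participants × 501 draws;
informativeness is checked on all 140 cohort participants × 500 draws
per cell; coverage/recovery use 500 matched-design replicates at 28
sets; null calibration uses 1500 single-week pipeline replicates; the
end-to-end deficit scenario uses 100 replicates. These sizes give
Monte-Carlo standard errors comfortably inside each tested band (e.g.
±0.5 percentage points on a 4–5% rejection rate).

## Known limitations

- The default PK parameters are representative, not estimates fitted to
  the original study's samples; absolute threshold values shift with the
  configuration, though the informativeness pattern is robust across the
  plausible range.
- Autoinduction is a step, not an enzyme-turnover process; weeks 0–2
  rifampicin concentrations in the generator are only approximate.
- Personalised thresholds condition on dose and fat-free mass but not on
  any individual concentration history (no empirical-Bayes step).
- The conditional-logit small-sample conservatism of Wald intervals is
  documented, not corrected; exact conditional inference is out of
  scope.
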