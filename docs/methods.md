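# Methods

This note documents the model implemented by `ros1ce`, its assumptions, the
defaults and why they were chosen, and the numerical conventions that matter
for reproducing its outputs.

## Survival layer

**Pseudo-IPD reconstruction.** A published Kaplan-Meier figure determines,
up to digitization error, the per-patient event history that produced it.
Two routes are implemented. For small studies every step drop and censor
tick is individually resolvable: a drop of size `d` at time `t` with `n`
patients at risk and survival `S⁻` just before encodes `round(n·d/S⁻)`
events, and a click at an unchanged level encodes one censored patient
(`replicate_small_study`). For larger studies the iterative Guyot inversion
is used: within each numbers-at-risk interval a censoring count is solved so
the implied risk set matches the table at the next interval start, censor
times are spread uniformly within the interval (optionally snapped onto
zero-drop clicks, which makes the two routes coincide on exactly-digitized
curves), and integer event counts are chosen so the reconstructed
product-limit curve passes through the digitized coordinates. Without a
risk table the total event count, or failing that a
censoring-only-at-last-follow-up assumption, anchors the inversion; the
method used per study is recorded in the pooled set's provenance map.
Curve cleaning clips survival to [0, 1] (inputs outside ±0.02 are rejected
as implausible digitizer jitter), collapses duplicate times to the last
click, enforces monotonicity by running minimum, and prepends the (0, 1)
origin. Ties put events before censorings, the standard KM convention.
Times are months throughout this layer.

**Parametric fitting.** The pooled two-arm data are fitted by maximizing the
right-censored log-likelihood `Σ δᵢ log f(tᵢ) + (1−δᵢ) log S(tᵢ)` on an
unconstrained scale (positive parameters log-transformed), Nelder-Mead
followed by a BFGS polish, with extra perturbed starts only on failure. The
treatment covariate enters as a hazard multiplier for exponential, Weibull
and Gompertz (PH-closed families) and as an acceleration factor for
log-logistic, log-normal and generalized gamma — the log-logistic family,
typically the best-fitting one here, is not PH-closed, so the "common
treatment parameter" is a time ratio there. The Wald covariance is the
inverse of a central-difference observed information; it is what the PSA's
correlated survival draws use. A Gompertz shape below zero (improper
survival, a plateau of never-progressors) is permitted but flagged, mirroring
the clinical-plausibility screen a modeller would apply. Model selection
minimizes AIC with BIC and then parameter count as tie-breaks, and always
reports the full ranking so visual inspection remains possible. The Cox HR
and the scaled-Schoenfeld PH score test (rank transform, α = 0.05) come from
lifelines, as the semi-parametric companion to the parametric fits.

## Decision model

Patients are identified by IHC screening with confirmatory FISH of positive
stains. With prevalence 1.64%, IHC sensitivity 100% / specificity 83%, FISH
100%/100%, IHC $42.36 and FISH $410.93, the expected cost per patient
screened is `c_IHC + P(IHC+)·c_FISH` and the cost attributed per true case
detected divides by `prev·sens_IHC·sens_FISH`. This testing cost is charged
once, to the crizotinib strategy only.

Detected patients enter a five-state cohort model — first-line PFS, second
line, third line, palliation, death — on one-week cycles (365.25/7 ≈ 52.18
cycles/year, 522 cycles over the 10-year horizon). The first-line exit
probability is derived directly at the cycle length from the fitted curve,
`1 − S(t+Δ)/S(t)` with `t` the model time; later-line and palliation exits
are exponential with medians 7.79 (platinum doublet after crizotinib), 3.26
(checkpoint inhibitor/docetaxel) and 4.60 months (palliative survival).
Exits split 70/10/20% (PFS → next line/palliation/death), 60/20/20% (second
line) and 60/40% (third line → palliation/death). Monthly quantities are
prorated by 7/30.4375.

Treatment within a state can differ, so sub-cohorts are tracked
explicitly: in the chemotherapy arm's first line (and the crizotinib arm's
second line, which is platinum doublet), patients still progression-free at
the end of induction — six 21-day cycles, 18 weekly cycles — split 50/50
into pemetrexed-maintenance and observation strata; the maintenance stratum
applies HR 0.62 to its per-cycle progression probability via
`1 − (1−p)^HR`. Age-within-state is carried by explicit induction
compartments, which also give each compartment a constant per-cycle cost.

Costing: crizotinib 2 × 250 mg tablets/day at $130/tablet ($1,820/week,
≈ $7,914/month) until progression; pemetrexed 500 mg/m² q21d at $0.21/mg with
BSA 1.75 m²; carboplatin dosed by the Calvert formula (AUC 5, creatinine
clearance 60 mL/min) with a $0 default unit price because the source tables
print none (configurable); later lines cost a 50/50 docetaxel
(75 mg/m² q21d, $0.27/mg) / checkpoint-inhibitor blend, the checkpoint
itself a 50/50 pembrolizumab (200 mg q21d, $44/mg) / nivolumab (3 mg/kg
q14d, 75 kg, $19.56/mg) mix — the doses are standard-of-care values, not
printed in the source tables, and all are configurable.
Administration-plus-monitoring costs ($1,176.83/month oral crizotinib,
$1,566.81/month IV regimens) accrue while on active treatment; observation
strata accrue no treatment cost. Palliation costs $3,124.07/month, and 50%
of the crizotinib arm additionally receives the later-line blend during
palliation (0% in the chemotherapy arm), reflecting the extra line of
therapy available to that arm. Adverse-event costs ($67.06 / $318.68) and
QALY decrements (−0.0194 / −0.0546) apply once at model entry. Utilities:
0.806 (PFS on crizotinib), 0.776 (PFS on chemotherapy), 0.660 (later
lines), 0.473 (palliation).

Both costs and outcomes are discounted at 1.5%/year at the cycle midpoint
(`(1+r)^−(c+0.5)Δ`), approximating continuous accrual; no half-cycle
correction is applied to transitions. Background non-disease mortality is
not added. `ICER = ΔC/ΔE`, with dominance flags instead of ratios when the
increments have opposing signs and an undefined flag when ΔE = 0.

## Uncertainty analysis

The PSA draws utilities, proportions and test characteristics from beta
distributions moment-matched to mean and SE (SE defaulting to 10% of the
mean, variance capped to keep the support; boundary means stay degenerate),
costs and medians from gamma distributions (SE 20% of mean), BSA from a
normal, the maintenance HR from a log-normal matched to its published 95% CI
(0.49–0.79), and the survival parameters jointly from a multivariate normal
using the Cholesky factor of the ML covariance (nearest-PSD eigenvalue clip
as fallback). Drug unit list prices are held fixed — they are administered
prices, not sampling uncertainty. None of the source dispersions are
published; these are conventional HE-modelling defaults and every one is
overridable. Transition-split draws sample the lead proportion and
rebalance the complementary destinations proportionally so each exit set
keeps summing to one. Per-simulation streams are spawned from the master
seed, so extending the simulation count leaves earlier draws unchanged;
failed evaluations are re-drawn from a reserved stream and counted, with a
1% failure cap. The CEAC is evaluated on a 0–$500,000/QALY grid (5,001
points).

The one-way DSA sweeps each parameter to low/high bounds (default ±20%,
clipped to [0, 1] where applicable) holding the rest at base case, and
sorts by ICER spread. The scenario engine applies named override sets to a
deep copy of the configuration — never mutating the base — including
structural variants: exponential PFS at the fitted medians, the
chemotherapy arm evaluated on the crizotinib curve ("no PFS difference"),
maintenance HR removed, a 4.2-month second-line median, equal or
ALK-proxy first-line utilities, 30% third-line uptake, and a combined
reanalysis. Scenarios requiring alternative survival inputs (individually
fitted arms) take them as explicit inputs and report clearly when absent.

## Synthetic benchmark

The generator emulates the pooled evidence base, not any real dataset:
study sizes {50, 80, 77} (crizotinib; only the 50-patient trial cohort size
is anchored to a published study) and {10, 12, 15, 18, 24} (chemotherapy),
log-logistic event times with medians 16.2 / 7.8 months, administrative
censoring from staggered accrual (uniform entry over the first half of
follow-up; data cuts 36 / 24 months). The truth's shape parameter 1.5 was
calibrated so the implied marginal Cox HR between arms centres near the
published pooled estimate of 0.47 — with medians fixed, a steeper shape
drives the early-time HR toward `(7.8/16.2)^shape` and the marginal HR well
below it. Small studies (n ≤ 25, configurable) are emitted as exact step
coordinates, larger ones on a 0.5-month click grid with Gaussian
survival-axis jitter (SD 0.005) and risk tables every 3 months. Per-study
seeds derive from the global seed, and identical seeds produce
byte-identical files.

What the generator does **not** emulate: between-study heterogeneity in
case mix (the source populations differed in prior lines of therapy and
could not be covariate-adjusted either), informative censoring, and the
actual shapes of the real digitized curves. Passing tests therefore
demonstrate that the machinery recovers known truths under realistic
sampling and digitization noise — not that the published base-case numbers
are reproduced, which the unprinted fitted survival parameters make
impossible in principle.

## Numerical conventions and edge cases

- Optimization tolerances: Nelder-Mead `fatol` 1e−8 on the log-likelihood,
  BFGS `gtol` 1e−6; covariance by central differences with steps
  `1e−4·(1+|θ|)`.
- Medians of fitted curves are found by bracketed root-finding on
  `S(t) = 1/2`; a curve plateauing above 1/2 has an infinite median (flagged
  improper for Gompertz).
- Trace rows are renormalized each cycle against floating-point drift and
  validated to sum to 1 within 1e−9; death occupancy must be non-decreasing.
- A PFS survival value ≤ 1e−12 treats the state as exhausted (exit
  probability 1) rather than dividing by zero.
- Event-count rounding in the Guyot inversion is clamped to the available
  risk set; intervals with no clicks censor their full decrement at the
  interval midpoint.
- On a time-grid digitization, events in the tail of a grid step surface at
  the following click; risk-interval conservation is therefore exact for
  exactly-digitized curves and approximate on coarse grids.

## Problem sizes used by the test suite

Simulation-based checks run at sizes chosen to make their Monte-Carlo error
small relative to the tolerance being asserted: parameter recovery at 200
replicates of 500 subjects/arm (~20% censoring), Cox-HR containment over 50
benchmark draws, selection consistency over 40 pooled-size replicates,
cohort-vs-microsimulation agreement with 100,000 simulated subjects, and a
500-simulation PSA for the acceptability threshold check.

## Known limitations

- The second- and third-line structure is deliberately coarse (exponential
  exits, blended comparator costs); real sequencing data would support a
  richer partitioned-survival or multi-state approach.
- Maintenance entry is modelled at a fixed 18-week induction boundary; in
  practice induction length varies.
- The same later-line utility applies to second and third line, and no
  utility decrement is carried for long-term toxicity.
- Administration/monitoring costs are attached to on-treatment states only;
  off-treatment progression-free patients accrue no monitoring cost.
- The generalized-gamma fit is the slowest (SciPy special functions) and
  occasionally needs its extra starts; its covariance can be near-singular
  when the data barely distinguish it from Weibull.
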