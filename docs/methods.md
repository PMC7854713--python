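# Methods

## Model

All stages assume single-phase first-order loss of a marker's
concentration after the source organisms are removed at time 0:

    C_t = C_0 · exp(−k t),    k ≥ 0 (1/h),  C in copies/mL.

Decay is fitted on the normalized response `log_e(C_t/C_0)`, whose
slope over the analysis window is `−k`. The window defaults to
0–72 h because empirical degradation curves are often biphasic (fast
early, slow late); restricting to the initial log-linear phase keeps
the single-exponential model honest. Half-life is `ln 2 / k`; its
95 % interval inverts the Wald interval endpoints `k ± z·SE` with
`z = 1.959964` (the exact Normal quantile). Because half-life is
strictly decreasing in k this is a monotone transform, valid only
when the k-interval excludes zero; the code refuses the inversion
otherwise and points at profile/bootstrap alternatives. A Student-t
quantile is available via the `df` argument — published half-life
tables are sometimes computed either way and differ in the second
decimal — but the Normal quantile is the default and is never
switched silently.

qPCR quantification is the standard log-linear calibration
`Cq = intercept + slope·log10(copies/reaction)`, amplification
efficiency `10^(−1/slope) − 1` (slope −log2(10) ≈ −3.3219 ⇔ 100 %),
and censoring of any reaction with Cq > 35 or no amplification.
Censored observations are carried as flagged non-detects, never as
zeros or imputed values, so each downstream stage owns its own
censoring policy.

## Estimators

**Two-stage decay estimator (default fallback, and the estimator used
by the Monte-Carlo studies).** Per tank×target series: OLS of
`log_e C′` on time over in-window detections (the normalization by
the observed C₀ shifts every response by a constant, so slope,
residuals and their variance are identical to the unnormalized fit
with a free intercept, and ordinary OLS inference applies). Per
target: slopes are pooled with time-leverage weights
(`w_i = Sxx_i`), the residual variance pooled across series; this is
algebraically the pooled OLS estimator with a fixed intercept per
series, `SE = sqrt(σ̂²/ΣSxx_i)`. With the balanced reference design
this gives ~50 residual degrees of freedom, so the z-based 95 %
interval attains ≈94–95 % coverage (verified by simulation in the
acceptance script). When every series contributes only two points
(zero residual df) the SE falls back to the between-series scatter of
slopes.

**Mixed-effects route (default when it converges).** `statsmodels`
MixedLM of `log_e C′` on time with per-target slopes
(`time × target`), a centered quantitative abundance covariate
entering both main effect and slope, and a random intercept per tank.
Per-target k and its SE come from linear combinations of the fixed
effects at the mean abundance. The likelihood is optimized with
Powell's method: gradient optimizers occasionally collapse into the
degenerate zero-residual-variance optimum (infinite likelihood),
which the code detects and rejects. Any convergence failure
downgrades to the two-stage estimator with a logged notice. The
initial-concentration model is the analogous fit to the t = 0
detections (`log_e C_0 ~ target + target×abundance_centered`, random
tank intercept), reporting per-target marginal means at the mean
abundance.

**Contrasts.** Group differences (mt vs nu genome, DNA vs RNA, rRNA
vs mRNA, short vs long fragment within a gene, abundance levels) are
z-tests on differences of (mean) estimates with Holm family-wise
adjustment. Holm was chosen because the estimates reaching this stage
are (estimate, SE) summaries rather than raw observations, which is
what a studentized-range (Tukey HSD) procedure would need; exact ties
report p = 1.

**Censoring policy.** Non-detects are dropped from decay fits (policy
`drop`; `refuse` errors instead). Near the detection limit this
truncates the low tail of the noise distribution and biases the
fitted slope toward zero — visible in the reference simulation for
the dilute DNA targets, whose true log-concentration path crosses the
detection limit inside the 72-h window. The package documents this
bias rather than correcting it; a censored-likelihood (Tobit) decay
model is future work.

## The ratio clock

For a marker pair the pooled OLS of `log10(C_num/C_den)` on time uses
only timepoints where both members are detections. Under the model
the R:D slope is `−(k_RNA − k_DNA)/ln 10` and the intercept is the
release baseline `b`. The age of a sample with observed log10 ratio
`r` is

    t̂ = ln(10)·(b − r)/(k_RNA − k_DNA),  clipped at 0,

undefined when `k_RNA ≤ k_DNA`. The confidence interval is a
percentile parametric bootstrap (default 2000 draws, fixed seed):
Normal draws of k_RNA, k_DNA, the baseline, and the observed ratio
from their standard errors, each draw inverted and clipped at 0.
Propagating the *observed-ratio* uncertainty (by default the ratio
regression's residual SD) is a deliberate extension beyond the three
parameter SEs: a single water sample's ratio carries the full
measurement noise, which dominates the estimator's error, and
omitting it would produce near-degenerate intervals with far below
nominal coverage. The `age_recovery_study` harness measures bias,
RMSE and CI coverage of the whole pipeline (fit decay constants and
baseline per replicate experiment, then age fresh noisy observations
at known true ages); with the reference noise level, aggregate
coverage sits near 94 % and RMSE grows with age, driven by the
uncertainty in the fitted rate difference. Age-0 clipping induces a
positive bias at young ages relative to the ~39 h estimator SD.

## Synthetic experiments

The generator emulates a tank (mesocosm) degradation study of
dreissenid mussels: abundance treatments {2, 6, 12, 24, 48} organisms
× 3 replicate tanks; sampling at 0, 5, 12, 24, 48, 72, 144, 240 h
after removal; ten gene×nucleic-acid targets (16S and COI
mitochondrial, 18S and histone H2B nuclear; rRNA and mRNA classes;
two fragment lengths each for 16S and H2B DNA) with reference
log_e initial concentrations {4.75, 4.42, 4.23, 6.43, 6.87, 6.75,
11.09, 7.31, 12.61, 2.03} and decay magnitudes {0.0378, 0.0420,
0.0398, 0.0466, 0.0461, 0.0480, 0.0561, 0.0602, 0.0735} per hour.
The H2B mRNA target has no measured decay constant (its
concentrations sit at the detection limit); the simulator takes a
fallback `h2b_rna_k = 0.09/h`, faster than every quantified marker,
consistent with its non-detection beyond about a day. The analysis
conventionally removes two compromised tanks
(`REFERENCE_EXCLUDED_TANKS`), leaving 13.

Generative structure per tank×target:

    c0_log = target c0 + 0.5·(ln a − mean ln a) + u,  u ~ N(0, 0.3²)
    k      = max(0, target k + 0.0003·(a − mean a))
    obs(t) = exp(c0_log − k·t) · exp(ε),  ε ~ N(0, 0.5²)
    censored ⇔ obs < 20 copies/mL

Abundance covariates are *centered* so that the treatment-averaged
realized parameters equal the configured per-target values — an
uncentered slope would shift every marginal intercept and decay
constant away from the reference numbers. The abundance slopes (0.5
log_e copies per log_e organism; 3·10⁻⁴ 1/h per organism) produce
monotone shedding and decay trends across treatments of the size the
design can detect; tank SD 0.3 and noise SD 0.5 on the log_e scale
are stated assumptions (no published variance components exist for
this design), and the 20 copies/mL floor is the Cq-35 rule mapped
through a 100 %-efficiency curve with intercept 40 and the default
volume bridge (2.5 µL template of a 75 µL eluate from 100 mL of
water filtered onto a half filter ⇒ 5/3 mL-equivalents per
reaction). Randomness uses one root seed with per-tank and
per-tank×target child streams, so adding a target never perturbs the
draws of another.

What the generator does **not** emulate: dynamic shedding before
removal (the 24-h accumulation is folded into c0), biphasic decay
(off by default; a `(breakpoint_h, multiplier)` switch multiplies k
after the breakpoint), temperature/pH/UV covariates, inhibition or
extraction efficiency, tank contamination events, and mixing of
material from multiple release cohorts. Passing recovery tests
therefore demonstrates correctness of the estimators under the
stated noise model, not robustness to all field conditions.

## Numerical choices

* Decay math in log_e, ratio math in log10; the conversion constant
  ln 10 is centralized in `ratio.LN10`.
* Floats in the tidy CSV are serialized with `repr` and parsed with
  round-trip precision, so write→read is bit-exact.
* Fitted k is floored at 0 (its magnitude parameterization); a
  negative fitted slope magnitude can only arise from noise at k ≈ 0.
* Series need a positive detection at t = 0 and ≥ 2 in-window
  detections to enter a decay fit; failing targets are reported as
  not-estimable with a reason, never raised.
* Bootstrap draws with non-positive Δk are discarded; if more than
  half are invalid the clock is declared unidentifiable.
* The reported age CI is widened, if necessary, to contain the point
  estimate (clipping can otherwise push a percentile past it).

## Problem sizes

The Monte-Carlo studies shipped with the package use 500 replicate
experiments for decay-constant recovery and coverage (13 tanks × 8
timepoints each), 200 replicates for the initial-concentration
recovery check, and 150–500 replicates for the age-recovery study —
sizes at which Monte-Carlo standard errors are a few percent of the
quantities checked.

## Known limitations

* No censored-likelihood decay model: dropping non-detects biases k
  near the detection limit (documented above).
* The clock assumes a single release pulse; environmental samples
  integrating material of mixed ages will read as an
  abundance-weighted pseudo-age.
* Ratio pairing requires both members quantified in the same water
  sample; no cross-sample calibration is attempted.
* Multi-plate qPCR calibration, inter-run calibrators and LOD/LOQ
  modelling beyond the fixed Cq threshold are out of scope.
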