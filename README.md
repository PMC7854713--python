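# ednaclock

Decay kinetics of environmental DNA and RNA, and an eRNA:eDNA ratio
clock for estimating the age of environmental genetic material.

## The problem

Environmental DNA (eDNA) surveys detect species from the genetic
material they shed into water, but a positive detection says nothing
about *when* the material was released: eDNA persists for days to
weeks, drifts with currents, and legacy signal produces false
inferences of presence. Environmental RNA (eRNA) decays faster than
eDNA, so the eRNA:eDNA ratio of a marker falls steadily after release
— which turns a pair of qPCR assays into a clock.

`ednaclock` is a library (plus a small CLI) for researchers analysing
replicated mesocosm degradation experiments: tanks stocked with a
known number of organisms, organisms removed at time 0, water sampled
on a fixed grid and assayed by qPCR for several gene markers in DNA
and RNA form. It covers the full path from Cq values to age
estimates, with a synthetic-experiment generator so that every stage
can be validated against known ground truth.

## The model

Concentrations follow first-order decay,

```
C_t = C_0 · e^(−k t),        C′ = C_t / C_0,
```

with `k` (1/h) fitted as the slope of `log_e C′` on time over the
initial log-linear phase (default 0–72 h), dropping qPCR non-detects
(Cq > 35). Half-life is `ln 2 / k`, with a Wald 95 % interval mapped
from `k ± 1.959964·SE`. Fits run either as a linear mixed-effects
model (per-target slopes, a quantitative abundance covariate, random
tank intercepts) or as a pooled two-stage per-tank OLS estimator.

For a marker quantified in both nucleic acids, the log10 RNA:DNA
ratio declines linearly with slope `−(k_RNA − k_DNA)/ln 10`, so an
observed ratio `r` against a release baseline `b` dates the material:

```
t̂ = ln(10) · (b − r) / (k_RNA − k_DNA)
```

with uncertainty from a parametric bootstrap over the decay
constants, the baseline and the observed ratio.

## Worked example

Simulate the reference mesocosm design (5 mussel-abundance treatments
× 3 tanks, 8 sampling times over 240 h, 10 gene × nucleic-acid
targets), drop the two compromised tanks, fit decay, and age a sample:

```python
import ednaclock as ec

cfg = ec.reference_config(seed=1)
series, truth = ec.simulate_experiment(cfg)
series = ec.exclude_tanks(series, ec.REFERENCE_EXCLUDED_TANKS)

res = ec.fit_decay(series, method="two_stage")
print(res.summary())

rs = [s for s in ec.build_ratio_series(series, "R:D") if s.pair[0].name == "16S_141"]
k_rna = res.fits[ec.GeneTarget("16S_141", "mt", "rRNA", 141, "RNA")]
k_dna = res.fits[ec.GeneTarget("16S_141", "mt", "rRNA", 141, "DNA")]
clock = ec.RatioClockModel(rs, k_rna=k_rna.k_hat, k_dna=k_dna.k_hat,
                           se_k_rna=k_rna.se_k, se_k_dna=k_dna.se_k).fit()
print(clock.summary())
age = clock.estimate_age(observed_log10_ratio=1.0, seed=1)
print(f"age of material at log10 ratio 1.0: {age.t_hat:.1f} h "
      f"(95% CI {age.ci_h[0]:.1f}-{age.ci_h[1]:.1f} h)")
```

prints (diagnostics go to stderr; abridged):

```
First-order decay fits (window 0-72 h, method=two_stage, censored dropped=186)
     target  k_per_h   se_k  half_life_h  half_life_lo_h  half_life_hi_h  n_obs
16S_141_DNA   0.0357 0.0045      19.4419         15.5933         25.8128     53
16S_341_DNA   0.0514 0.0065      13.4961         10.7989         17.9892     49
...
16S_141_RNA   0.0558 0.0024      12.4151         11.4651         13.5367     78
18S_169_RNA   0.0733 0.0024       9.4510          8.8891         10.0888     78
H2B_250_RNA      NaN    NaN  (not estimable: no positive detection at t = 0)
abundance effect on k: +3.291e-04 1/h per organism (se 5.5e-05)

log10 Ratio_R:D ~ time: slope -0.01044/h (se 0.00234), intercept 2.703,
R^2 0.281, p 4.43e-05, n 53
age of material at log10 ratio 1.0: 194.3 h (95% CI 117.5-391.1 h)
```

The fitted decay constants recover the generating values (e.g. 16S
rRNA truth 0.0561/h, estimate 0.0558/h), the RNA:DNA ratio declines
significantly, the low-copy histone mRNA target is correctly reported
as not estimable, and the clock dates a sample whose RNA:DNA ratio
has fallen from ~10^2.7-fold to 10-fold excess at roughly eight days.

The same steps are available from the shell:

```
ednaclock simulate --seed 1 --out mesocosm.csv
ednaclock fit --in mesocosm.csv --window 0:72 --out fits.json
ednaclock ratio --in mesocosm.csv --kind RD --out ratios.csv
ednaclock age --ratio 1.0 --baseline 2.7 --k-rna 0.0561 --k-dna 0.0378
```

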