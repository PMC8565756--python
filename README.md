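# cndc — critical nitrogen dilution curves for double-cropped rice

`cndc` builds, validates and applies **critical nitrogen (N) dilution
curves** for nitrogen-rate field trials, using **leaf dry matter (LDM)**
as the biomass basis. It is aimed at agronomists and crop modellers who
diagnose crop N status from plant sampling data: the package turns
plot-level observations (LDM, plant N concentration, N rate, growth
stage) into a fitted dilution curve, nitrogen nutrition indices, and a
yield-response optimum.

## The model

The critical N concentration is the minimum plant N concentration that
still permits maximum growth at a given biomass. It declines as the
canopy accumulates dry matter ("dilution") following a power law

```
Nc% = a · LDM^(-b)
```

where `a` is the critical N concentration (% of dry weight) at
LDM = 1 t·ha⁻¹ and `b` the dimensionless dilution exponent.

The curve is constructed date by date with the Justes procedure:

1. **Classify** — at each sampling date, split N treatments into
   N-limited and non-N-limited groups, either by one-way ANOVA of LDM on
   N rate followed by Tukey–Kramer comparisons against the maximal-LDM
   treatment (replicate data), or by published significance letters
   (treatment means).
2. **Oblique line** — OLS of plant N concentration (PNC) on LDM through
   the limited treatments.
3. **Vertical line** — at the mean LDM of the non-limited treatments
   (the date's maximum attainable leaf biomass).
4. **Critical point** — the intersection `(LDMmax, Nc)` of the two lines.

Critical points from all usable dates are pooled and the power law is
fitted, by default as OLS on the linearised form
`ln Nc = ln a − b·ln LDM` (a nonlinear least-squares fit on the original
scale is available). Curves of two groups are compared by ANCOVA-type
F-tests on the linearised scale (equal slopes, then equal intercepts
under a common slope).

Downstream diagnostics:

* **NNI** (nitrogen nutrition index) `NNI = Na / Nc` — measured over
  critical N concentration; 1 is optimal, below 1 deficient, above 1
  luxury uptake;
* **validation** of a curve against independent critical points via RMSE
  and n-RMSE (= 100·RMSE/mean observed), classed
  excellent/good/moderate/poor at the 10/20/30 % thresholds;
* **yield response** — quadratic fit of relative yield (yield over the
  season's best yield) on NNI; the vertex gives the NNI at which
  relative yield peaks.

A synthetic-trial generator (`cndc.simulate`) draws replicate-level
trials from a known power law with a saturating biomass response to N
rate, sub-critical N-limited treatments, luxury uptake, lognormal
replicate noise and a quadratic yield response, so the whole pipeline
can be tested against known ground truth.

## Worked example

The package ships the published treatment-mean table of a two-year
double-cropped rice N-rate trial from Jiangxi, China (2 seasons ×
2 varieties × 5 growth stages × 4 N rates, means ± SE with P<0.05
grouping letters). Running the full construction on it:

```sh
cndc run-all --input fixture --method letters --outdir results/
```

prints

```
observations: 80
usable dates: 20 / 20
critical points: 20
curve [early]: Nc% = 2.988 * LDM^(-0.7786)  R2=0.7309  (n=10, loglog_ols)
curve [late]: Nc% = 7.356 * LDM^(-1.29)  R2=0.7481  (n=10, loglog_ols)
compare early vs late: p_slope=0.2121 p_intercept=0.006941 -> different
```

Every sampling date of the table supports the construction (20 usable
dates), each contributing one critical point. The pooled early-rice
curve has `a` ≈ 2.99 — at 1 t·ha⁻¹ of leaf dry matter the crop needs
about 3 % N in the plant to grow at its maximum — and the late-rice
curve dilutes much faster (`b` ≈ 1.29 vs 0.78): the late season's warmer
conditions speed up biomass accumulation relative to N uptake. The
ANCOVA comparison finds the two seasons' curves significantly different
(intercept test p ≈ 0.007), supporting separate early- and late-season
curves.

The same analysis is available as a library:

```python
import cndc

table = cndc.load_table2_fixture()
points = cndc.extract_points(table.subset(season="early"), method="letters")
curve = cndc.fit_curve(points)          # a=2.988, b=0.779
nni = cndc.nni_records(table.subset(season="early"), curve)
```

Synthetic end-to-end check with known truth:

```sh
cndc simulate --seed 7 --out trial.csv --truth-out truth.txt
cndc run-all --input trial.csv --method anova --outdir synth_out/
# recovers Nc% = 2.988 * LDM^(-0.5055) for a_true=3, b_true=0.5
```

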