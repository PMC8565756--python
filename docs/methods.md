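# Methods

## Model and assumptions

The package implements the Justes-type construction of a critical
nitrogen dilution curve on a leaf-dry-matter basis. The underlying model
is the allometric power law `Nc% = a · LDM^(-b)` (`a` in % N at
LDM = 1 t·ha⁻¹, `b` dimensionless). Its assumptions, inherited by every
downstream diagnostic:

* at each sampling date there exists a maximum attainable leaf biomass,
  reached by the non-N-limited treatments;
* among N-limited treatments, PNC varies approximately linearly with
  LDM over the (narrow) within-date biomass range, so an OLS line
  through the limited treatment means extrapolates meaningfully to the
  non-limited biomass;
* the resulting per-date critical points follow a single power law over
  the season (one curve per season/variety group; no year or stage
  interaction beyond what pooling absorbs).

## Construction choices

* **Classification.** Replicate data: one-way ANOVA of LDM on N rate
  gates the date (no global signal at level α → all treatments
  non-limited, date unusable); then each treatment is compared with the
  maximal-LDM treatment by Tukey–Kramer HSD (pooled within-treatment
  variance, studentized-range critical value; critical values cached by
  (α, k, df)). Treatment means with letters: a treatment is non-limited
  iff it shares at least one LDM letter with the maximal-LDM treatment
  (compact-letter-display semantics; multi-letter labels belong to all
  their groups). Exact ties for the maximal mean are all non-limited.
  α defaults to 0.05, matching the P<0.05 letters of published tables.
* **Usability.** A date contributes a critical point only with ≥ 2
  limited and ≥ 1 non-limited treatments; other dates are skipped
  silently (counted in the pipeline log).
* **Oblique line.** Fitted to treatment means (one point per N rate),
  not replicates, matching published-mean inputs; a negative or zero
  slope is allowed with a warning rather than rejected — rejecting
  would bias the curve by silently discarding low-signal dates.
  A warning is also emitted when the intersection falls outside the
  date's observed PNC range (extrapolation).
* **Vertical line.** Arithmetic mean LDM of the non-limited treatments.

## Curve fitting and comparison

* Default fit is OLS on `ln Nc ~ ln LDM` (`loglog_ols`), the same scale
  on which between-group inference runs; `nonlinear_ls`
  (Levenberg–Marquardt on the original scale, initialised at the
  log-log solution) is available. R² is always computed on the original
  Nc scale, so the two methods are comparable.
* No low-biomass plateau is applied: the power law is evaluated
  everywhere, with a warning outside the fitted LDM range.
* Group comparison is sequential ANCOVA on the linearised scale: F-test
  of the slope×group interaction (equal dilution exponents), then,
  under a common slope, F-test of the group effect (equal `ln a`). The
  verdict is "different" iff either p < α. Note that this verdict is a
  union of two α-level tests: its familywise null rejection rate is
  ≈ 2α−α² (about 0.10 at α = 0.05), deliberately more sensitive than
  either constituent test. Each constituent F-test is exactly
  calibrated under lognormal multiplicative noise. When the pooled
  regression fits to numerical exactness (e.g. duplicated noise-free
  point sets), p-values are decided directly from the sums of squares
  instead of a 0/0 F ratio.

## Diagnostics

* **NNI** is computed per treatment with the critical concentration
  evaluated at the treatment's *own* mean LDM (a `date_max` switch
  evaluates all treatments of a date at the date's maximal LDM
  instead). Strict optimality (NNI = 1) has probability zero on real
  data, so status uses a configurable band, default 0.95–1.05; the
  strict rule is the band (1, 1).
* **Validation** predicts Nc from the holdout points' maximum LDM and
  compares with the holdout critical concentrations (never the reverse
  regression). n-RMSE = 100·RMSE/mean(observed); stability classes use
  half-open intervals [0,10) excellent, [10,20) good, [20,30) moderate,
  [30,∞) poor — the conventional verbal thresholds leave the exact
  boundaries undefined, so boundaries are assigned upward.
* **Yield response.** Relative yield is each treatment's yield over the
  maximum of its season-year group. The quadratic RY-on-NNI fit reports
  the closed-form vertex; an upward-opening fit (c₂ > 0) is flagged
  (`is_maximum = False`) and its vertex reported as a minimum. The
  growth stage whose NNI is used is a parameter; when unset, the
  pipeline fits every stage with enough data and keeps the best-R²
  stage (seasonal data typically peak at heading or booting).

## Synthetic-trial generator

The generator emulates exactly the structure the analysis assumes, so
parameter recovery is a meaningful end-to-end test:

* mean LDM per (stage, rate) = stage potential × saturating rate effect
  `(f₀K + r)/(K + r)` (fraction `f₀` of potential at zero N, half the
  remaining gap closed at rate K);
* treatments at ≥ 95 % of potential are non-limited; their mean PNC is
  `luxury_margin` × the curve at their own LDM (luxury uptake);
* limited treatments lie on the line through the stage's true critical
  point with slope `sub_slope_factor · Nc*/LDM*` — a locally linear
  sub-critical relation strictly below the curve, so noiseless
  extraction reproduces the true curve exactly;
* replicates multiply means by independent lognormal noise of mean 1
  and the configured CV (LDM and PNC independently), keeping values
  positive with roughly constant CV, as in published SE/mean ratios
  (~2–10 %);
* plot yields follow the configured quadratic RY(NNI) at a reference
  stage, scaled by a maximum yield, with the same noise model.

Defaults: `a=3.0`, `b=0.5`, rates (0, 25, 150, 225) kg·ha⁻¹, stage
potentials 0.9/1.5/2.2/2.6/2.4 t·ha⁻¹ (TS…FHS), K = 10 kg·ha⁻¹,
f₀ = 0.25, luxury margin 1.1, sub-slope factor 0.8, CV 5 %,
3 replicates, RY coefficients (0.40, 1.10, −0.55) (vertex at NNI 1.0,
RY 0.95), maximum yield 8 t·ha⁻¹. The rate grid and half-saturation
are chosen jointly so that the trial has the clean two-group structure
the classification requires: with a Michaelis-type response, the two
top rates sit on the biomass plateau (≥ 95 % of potential) only for
small K, and the sub-plateau rate must then sit well below the plateau
(~18 % here) to be resolvable by ANOVA with 3 replicates at 5 % CV.
The seed is a required argument of the public API (CLI default 0).

What the generator does **not** emulate: weather and soil processes,
within-season growth dynamics (stage potentials are set directly),
spatial field heterogeneity, correlated errors between LDM and PNC, or
measurement error in N rate. Passing recovery tests therefore show the
statistical machinery is correct under the model's own assumptions, not
that the model fits any particular field dataset.

## Packaged data and what it reproduces

The packaged fixture transcribes the published treatment-mean table of
the Jiangxi double-cropped rice trial (80 mean-level rows: LDM and PNC
means ± SE with P<0.05 letters; early rates 0/75/150/225, late
0/90/180/270 kg·ha⁻¹). The table does not state which trial year (or
pooling of years) it represents, so the fixture records the year as
missing. Running the construction on it reproduces the published
*pooled-season* curves within the documented tolerances (early
a = 2.99 vs 2.66, b = 0.78 vs 0.79; late a = 7.36 vs 7.46, b = 1.29 vs
1.42). The published *single-variety* coefficients (labelled as 2019
fits) are **not** reproduced from this table (e.g. 'Taiyouhang 1573'
a = 14.4 vs 6.58): its single-variety critical points — particularly
the early-stage points of the late varieties, which extrapolate above
the observed PNC range — cannot be the data behind those fits. The
corresponding checks are kept failing rather than loosened. The
published per-variety holdout RMSE/n-RMSE values likewise require the
unpublished plot-level holdout data; the package exercises that
computation pathway on synthetic trials instead.

## Numerical choices and test problem sizes

* Observation round-trips are exact up to float text representation
  (tested at 1e-9); oblique/vertical intersections satisfy
  `nc = intercept + slope·ldm_max` exactly by construction.
* Degenerate inputs raise typed errors: < 2 oblique points or zero LDM
  variance, < 3 curve points, all-equal ln LDM in a comparison group,
  rank-deficient quadratic designs, non-positive inputs to NNI/n-RMSE.
* Calibration and recovery tests use: 500 synthetic trials for
  parameter recovery (median â within ±10 %, median b̂ within ±0.1),
  200 random dates for classification-oracle agreement (≥ 99 %),
  1000 null and 200 alternative simulations for the comparison tests,
  and 200 simulations for the 5 %-noise validation check — sizes chosen
  to keep Monte-Carlo error well below the tested margins.

## Known limitations

* The oblique line uses treatment means; replicate-level uncertainty in
  the critical points is not propagated into the curve fit (no
  errors-in-variables correction).
* One curve per group: no hierarchical pooling across varieties/years.
* The NNI band and the 95 % plateau threshold are conventions, not
  estimates; sensitivity to them is not quantified.
* Yield attaches one harvest value per plot; stage-resolved yield
  formation is out of scope.
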