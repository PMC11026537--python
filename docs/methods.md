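# Methods

This note documents the models and procedures `reefstress` implements, the
choices made where the field's conventions leave room, and what the
synthetic-data generators do and do not emulate.

## Thermal-stress metrics

**Accumulated Heat Stress (AHS, °C-weeks).** Logger samples (nominally every
20 minutes) are summarised into local calendar days (UTC−10, so the diurnal
cycle never straddles midnight), then into consecutive 7-day blocks anchored
at the start of the analysis window (default 1 August, the bleaching-year
start). A week qualifies when its mean reaches the Maximum Monthly Mean
(MMM, 29.0 °C for Moorea) plus a 0.1 °C gate; a qualifying week contributes
its full excess above the MMM, and AHS at week *w* is the sum of
contributions over the 12 most recent weeks. The alternative reading — a
qualifying week contributes only its excess above 29.1 °C — is available as
`gate_mode="excess"`; the default follows the hotspot convention in which
0.1 °C is a qualification gate, not part of the magnitude.

Anchoring weeks at the analysis-window start (rather than ISO calendar
weeks) makes the metric reproducible and independent of weekday
conventions. Weeks with fewer than 12 predecessors carry a partial sum
flagged *warm-up* and are excluded from the reported maximum by default, so
a record that begins mid-heatwave cannot claim a spuriously small running
sum as its peak.

**Quality control.** A day is *complete* with ≥ 80 % of the samples
expected at the nominal interval (a common logger-QC convention; the
fraction is configurable). A week is valid with ≥ 6 of 7 complete days.
Under the strict gap policy (default) an AHS value is undefined whenever
any of its 12 weeks is invalid — mirroring the conservative practice of
discarding discontinuous loggers outright — while the lenient policy
rescales the valid-week sum by 12/valid-count. Whole loggers are classified
continuous/discontinuous over the analysis window by a gap scan (any gap
above `max_gap`, default 6 h, or overall completeness below 90 % fails);
discontinuous loggers propagate downstream as absences, never zeros.

**Mean Daily Temperature Fluctuation (MDTF, °C)** is the mean of the daily
range (max − min) over complete days in a window, by default
15 February – 15 March 2019, the month before bleaching was first observed
(15 March is adopted as the onset date; the true onset is unknown). MDTF is
offset-invariant and scales linearly with deviations around the daily mean.

**Climatology envelope.** The multi-year day-of-year mean uses a 365-day
index with 29 February merged into 28 February (the convention of most reef
climatology products) and a t-interval on the across-year SD, reported for
days with at least two contributing years.

**Depth labels.** Loggers deployed at 20 m are relabelled to the 17 m
analysis isobath at ingest, matching how the deployment depth and the
surveyed isobath are reconciled in practice.

## Survey processing

A colony is *severely bleached* when bleached + recently-dead cover is
≥ 75 % (inclusive; the two conditions are pooled). Size classes are
small 5–9 cm, mid 10–29 cm, large ≥ 30 cm on visually estimated maximum
diameters; because divers bin to whole centimetres, continuous diameters
are rounded half-up to a whole cm before the half-open intervals
[5,10), [10,30), [30,∞) apply — hence 9.5 cm reads as 10 cm (mid) and
rounded diameters below 5 cm are out of survey scope (excluded with a
warning, not an error).

Aggregation produces one row per site × depth × genus × size class with
`n`, `n_severe`, `pct_severe` and a standard error. The SE convention on an
aggregated percentage is not uniquely determined; the default is the
binomial SE 100·√(p(1−p)/n) on the cell's colonies, with the
transect-replicate alternative (SD of transect proportions over
√n_transects) selectable — outputs record which was used. Cells whose
site × depth has no heat-stress value (e.g. its logger failed QC) are
excluded and listed; empty size-class cells are flagged, never silently
dropped. Survey widths differ by genus in the field (intercept-only vs
1-m swath), which affects density comparability, not these computations.

## Inference

**Depth t-tests.** The 10 m vs 17 m comparisons of maximum AHS and MDTF use
the two-sample t statistic with a 95 % CI on the mean difference. With
equal group sizes the pooled and unpooled statistics coincide and only the
degrees of freedom differ; `df_method="pooled"` (default) reproduces
t-distribution intervals at df = n₁+n₂−2, with Welch–Satterthwaite df
available. (The published intervals for these comparisons are exactly the
pooled-df intervals, so pooled is the reproduction default.)

**Linear mixed model.** Per genus, `pct_severe` (untransformed percent, as
is conventional for this analysis; the GLMM covers the principled
alternative) is modelled with fixed effects depth (two-level factor,
reference 10 m), centered AHS, size class (ordered factor, treatment coding
with reference small — pairwise level comparisons are the reported
quantity), and size × AHS; site is a random intercept and nothing more.
AHS centering (at the observed mean, summed in sorted order for exact
row-order invariance) aids interaction interpretability and does not change
the tests reported here.

Estimation is REML via an exact one-dimensional profile over the
site-to-residual variance ratio γ = τ²/σ² (σ² profiles out in closed form),
minimised to |Δγ| ≤ 1e−12; this makes the fit deterministic and row-order
invariant, and the same criterion supplies the curvature the Satterthwaite
approximation needs. A site variance at the zero boundary is reported
explicitly (`boundary=True`). statsmodels MixedLM serves as an independent
cross-check in the test suite.

**Type II Wald tests.** Each term is tested after all other terms except
its higher-order relatives, via the projection-corrected hypothesis matrix
(on balanced orthogonal designs this reduces to selecting the term's
coefficients, and Type II F equals sequential Type I F). Denominator df use
the Satterthwaite approximation: for a scalar contrast,
df = 2g²/(∇gᵀ·Var(θ̂)·∇g) with g(θ) = ℓᵀC(θ)ℓ and Var(θ̂) from the observed
REML information; multi-df terms combine per-eigendirection df as
2E/(E−q), E = Σνᵢ/(νᵢ−2). `df_method="residual"` is available;
Kenward–Roger is recognised but not implemented (it requires the full
small-sample-adjusted covariance machinery), and the output always names
the method used. Because both scales appear in the field's reporting, each
term also carries the asymptotic Wald χ² (= F × num df) with its χ²
p-value.

**Marginal means.** Factor-level means average the other factor's levels
with equal weights and hold centered AHS at 0 (its observed mean); since
the model is linear in AHS, evaluating at the mean and averaging over
observed values give identical means, so the distinction matters only for
back-transformed GLMM summaries. Pairwise contrasts use the
studentized-range (Tukey) adjustment at the contrast's Satterthwaite df;
the adjusted p-value is floored at the unadjusted one, which it can never
mathematically undercut anyway.

**Binomial GLMM.** The colony-level severe indicator is modelled with the
same fixed and random structure under a logit link, by maximum likelihood
with per-site adaptive Gauss–Hermite quadrature (15 nodes re-centered at
each site's conditional mode with Laplace curvature — the nAGQ approach;
no frequentist random-intercept binomial GLMM exists in the installed
Python stats stack, so the integrator is implemented here). Colonies with
identical covariates are collapsed to binomial counts first, making the
fit cost independent of colony count. Errors are raised on a single
outcome class and on apparent complete separation (a diverging
coefficient, reported by name). When the site SD collapses to ~0 the
log-σ information direction is flat; coefficient covariance then falls
back to the fixed-effects information block.

**Qualitative agreement.** The LMM (percent scale) and GLMM (logit scale)
are compared by sign and by per-term Type II significance. Signs are
additionally summarised over *resolved* coefficients — those at least one
path distinguishes from zero at α — because the sign of an effect neither
model can resolve is sampling noise, not qualitative disagreement. The
report exposes both the raw and the resolved sign-agreement fractions.

## Synthetic data

**Temperature.** Each site × depth series is seasonal sinusoid + diurnal
cycle + bounded AR(1) high-frequency oscillation + raised-cosine heatwave
anomaly + white measurement noise, sampled on a 20-minute grid with
configurable dropout gaps; every cell has an independent child RNG stream,
so outputs are bit-for-bit reproducible from (scenario, seed) and adding a
cell perturbs nothing else. The AR(1) term is a statistical stand-in for
internal-wave variability (larger SD at 17 m, giving the deeper isobath
the larger MDTF; the shallow cells get the larger diurnal amplitude) — it
is not a physical internal-wave model, and no irradiance, tide, or
advection structure is represented. The bleaching-year preset's per-cell
heatwave peaks are calibrated, on the deterministic components, so each
realized maximum AHS tracks its published per-cell value (spanning roughly
4.1–6.1 °C-weeks).

**Colony surveys.** Severity is Bernoulli on a logit-linear predictor
(genus intercept, size effects, depth effect, AHS slope, size × AHS
slopes, Gaussian site intercept), with AHS centered over the lookup's
cells. Severe colonies draw bleached+dead uniformly on [75,100] and
non-severe on [0,74.5], splitting up to 30 % of the total as recently
dead — a documented free invention (the data only constrain the ≥ 75
boundary), so within-colony composition should not be analysed as
realistic. The two genus presets reproduce the qualitative contrast the
analysis is built to detect: a thermally sensitive genus (high baseline,
strong shallow-water excess, no AHS slope) and a tolerant genus (low
baseline, strong large-colony × AHS interaction). The study-scale preset
carries exactly 3,227 + 1,874 = 5,101 colonies over 16 transects. Default
coefficients are qualitative, not fitted to any published figure.

**Cell-level severity tables.** For LMM calibration (parameter recovery,
interval coverage, type-I error) truth must exist on the percent scale, so
a Gaussian generator draws `pct_severe` directly from the LMM's own
generative form (known coefficients, site SD, residual SD) over the eight
published site × depth heat-stress values × three sizes (24 rows). A
colony-level logit generator cannot serve here: inverse-logit nonlinearity
means its coefficients induce no exact percent-scale truth. Consequently
the calibration results certify the inference machinery under the model's
own assumptions; they do not certify robustness to the binomial
heteroskedasticity real cell percentages carry (the GLMM path, validated
by coefficient recovery against logit-scale truth, is the model that
matches that data-generating process).

## Problem sizes and numerical settings

Calibration suites run at 100 replicates (coverage over 700
coefficient-interval trials, and interaction type-I error) and the
LMM/GLMM agreement study at 200 replicates of ~1,200 colonies; these sizes
put the Monte-Carlo binomial error well below the effects being checked
while keeping the default suite quick. REML profile tolerance 1e−12 on γ;
GLMM optimisation by BFGS on numerical gradients (gtol 1e−6) with a
Nelder–Mead polish fallback; numerical Hessians by central differences
with relative step 1e−4; quadrature at 15 nodes. Fits are deterministic
given the input table (rows are canonically sorted internally), and all
generator randomness flows from explicit seeds.

## Known limitations

- Kenward–Roger denominator df are not implemented; Satterthwaite is the
  default and the difference is immaterial to the calibration surface here.
- The LMM treats cell percentages as homoskedastic Gaussian; cells with few
  colonies violate this, which is precisely why the colony-level GLMM is
  run alongside and compared qualitatively.
- The temperature generator's realism is statistical (spectra-free AR(1),
  fixed-shape heatwave); it supports metric and pipeline validation, not
  physical inference.
- MDTF is computed but deliberately not entered into the mixed models
  (it is collinear with depth and AHS in this design).
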