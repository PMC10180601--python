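# Methods

## Chronology model

A tree's two core series are arithmetically averaged into its mean
radial growth series (RGS); years measured on only one core use that
core's value (missing rings are "absent", never zero growth), and
single-core trees are accepted with a logged warning. Species raw
chronologies (RGC) are per-year arithmetic means over RGS, keeping only
years with at least `min_depth = 2` trees. Ar1 — the hold of the
previous year's growth on the current year — is the biased
autocovariance-ratio estimator
r1 = Σ_{t≥2}(x_t−x̄)(x_{t−1}−x̄) / Σ(x_t−x̄)², computed on the raw
chronology by default (a detrended variant is available; the raw series
is the conventional base for this statistic).

### Spline detrending

The age/size trend of each RGS is a penalised cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`) with the smoothing parameter
derived analytically from the frequency-response criterion: for the
squared-second-derivative penalty the stationary response at angular
frequency ω is 1/(1 + λω⁴), so requiring gain a at wavelength p gives
λ = (1/a − 1)/(2π/p)⁴. Defaults: a = 0.5 at p = 0.67·n (series length n),
the standard flexible choice that removes the age trend while passing
interannual variation. Growth indices are ratios measured/fitted;
non-positive fitted values abort with the offending year rather than
being clamped.

**End-effect caveat.** The 50 % gain is an interior (stationary)
property of the filter. Verified by a numeric oracle — fit a sinusoid of
the cutoff wavelength on a carrier series ten wavelengths long and
project the interior of the fit onto the sinusoid — the gain is 0.500
for n ∈ {50, 100, 200}. Measured over a whole series of length n
(where the cutoff wavelength fits only ~1.5 times), the apparent gain
rises to ~0.65 because the spline tracks the data near the boundaries;
this is an edge transient common to every correctly parameterised
smoother (we checked discrete Whittaker, reflective/DCT and natural
cubic-spline variants), not a parameterisation error. Practitioners
know it as end-effect trend distortion.

### Chronology aggregation and quality

Per year (depth ≥ 2) the growth index chronology (GIC) is Tukey's
biweight robust mean (c = 9, tolerance 1e-6, median/MAD start; MAD = 0
falls back to the median; two points reduce to the arithmetic mean).
Rbar is the mean pairwise Pearson correlation over each pair's common
years (pairs with < 10 common years are skipped); EPS uses the Wigley
form n·Rbar/(n·Rbar + 1 − Rbar) with n the mean per-year sample depth —
the depth convention is not standardised, so it is stated here and fixed
in code.

## Climate indices

Windows: calendar months, vegetation period VP = current April–September
(183 days), previous winter PW = previous October–current March.
Aggregation is the mean (temperatures, VPD) or sum (precipitation, heat
sum) over the window's days; a window with more than 5 % of days missing
(configurable) yields NaN rather than a biased value — this replaces
station splicing/gap-filling, which is out of scope.

Thresholds (all configurable, defaults as conventionally defined): heat
sum base 20 °C (strict >), hot days Tmax ≥ 30 °C, frost days
Tmin ≤ 0 °C, ice days Tmax ≤ 0 °C, rain days PPT > 1.0 mm (strict).

**VPD.** e_s(T) = 6.1078·exp(17.27·T/(T + 237.3)) hPa (Magnus over
water; the constant triple is an assumption documented here — other
Magnus variants differ by < 1 % in the relevant range), e_a = RH/100·e_s,
VPD = e_s − e_a. Monthly/VP values average the daily maxima; with
sub-daily data the daily maximum is taken over the samples, otherwise it
falls back to e_s(Tmax) with the daily mean RH, which slightly
overstates the maximum deficit on days when humidity and temperature
peak together.

**Thornthwaite PET.** Annual heat index I = Σ(T_m/5)^1.514 over months
with T_m > 0; a = 6.75e-7·I³ − 7.71e-5·I² + 1.792e-2·I + 0.49239;
PET_m = 16·(10·T_m/I)^a·L_m mm, zero for freezing months, with L_m the
day-length correction (N/12)·(days/30) from the standard solar
declination formula at the site latitude (default 49.93° N).

**SPEI3.** Climatic water balance D = PPT − PET per month, summed over a
3-month backward window assigned to the ending month. Per calendar
month, a three-parameter log-logistic distribution is fitted over the
calibration years by unbiased probability-weighted moments, via
L-moments in the generalized-logistic parameterisation (κ = −τ₃): this
is the log-logistic for positively skewed balances and remains well
defined for near-symmetric or negatively skewed samples, where the
direct shape-parameter formulas lose the sign of a small denominator at
calibration sizes of 26–60 years. The CDF value is mapped to a standard
normal deviate. Calibration defaults to all available years; fewer than
30 calibration years warns. Drought classes: moderate −1.00…−1.49,
severe −1.50…−1.99, extreme ≤ −2.00.

**Stress years.** Primary criteria: VP mean temperature ≥ 90th
percentile and VP precipitation ≤ 10th percentile over the study years;
percentiles use linear interpolation between order statistics, so with
ties every tied year flags (inclusive comparisons). Confirmation flags:
hot days/heat sum/VPD ≥ their 90th percentiles, rain days ≤ 10th, and
VP-average SPEI3 < −1 (the VP value of SPEI3 is defined as the
April–September mean of the monthly index). First/last years whose
windows are not covered by the record are excluded by the
window-completeness rule, not by hard-coded years.

## Correlation functions

The design matrix pairs the GIC with every (variable, window) cell from
previous-year September to current-year September (previous-year months
lag the climate table by one calendar year) plus the VP/PW aggregates
each variable is defined on. Leading years without lagged climate are
dropped row-wise when enough years remain; constant columns (e.g. summer
ice days) are dropped with a warning. Reported r is the full-sample
Pearson coefficient; the bootstrap (1000 pair resamples, percentile
2.5/97.5 bounds) supplies only the confidence interval, and significance
means the interval excludes zero. Each cell's resampling stream is
spawned deterministically from the top-level seed, so results are
bit-reproducible and independent of cell order. No multiple-testing
correction is applied across cells (each cell is tested at its own 5 %
level) — a deliberate mirroring of common correlation-function practice,
and a caveat: with ~75 cells, ~8 % of null cells flag at n = 26 (the
percentile bootstrap is slightly anti-conservative at this sample size;
measured null rate ≈ 8 % against the nominal 5 %).

## Resilience indices

Computed per tree on raw RGS ring widths (ratio indices are
scale-invariant, so units cancel); a flag allows detrended indices for
sensitivity analysis. Window width 1 uses single pre/post years; width 2
uses two-year arithmetic means, balancing out single favourable or
unfavourable years. Events whose windows extend beyond the series are
excluded by window completeness (a 2018-like event with a record ending
in 2019 simply has no width-2 row). Rl = Rs·Rc holds exactly by
construction; the test suite verifies it to machine precision.

Species summaries report medians. Two across-event conventions are
exposed side by side, because they differ and the field's descriptions
are ambiguous: `avg_of_event_medians` (median of the per-event species
medians) and `pooled_median` (median over all per-tree-per-event
values). Group differences use Kruskal–Wallis (tie-corrected) with
Dunn's pairwise z from mean ranks, Holm–Šidák adjusted, rejecting at
p_adj ≤ α/2; size/growth comparisons use one-way ANOVA with Tukey HSD.
Dunn's test is implemented in-package (mean-rank z with the standard tie
correction) and validated against hand-computed oracles.

## Synthetic data generator

**Climate.** Daily mean temperature = seasonal cosine (annual mean
8.2 °C, amplitude 9.4 °C, peak at day 200) + AR(1) anomalies (φ = 0.7,
innovation sd 3 °C); Tmin/Tmax at ±5.5 °C around the mean with 1 °C
jitter; precipitation as wet-day Bernoulli (p = 0.5) × gamma amounts
targeting 741 mm/year and 399 mm in the vegetation period; relative
humidity anti-correlated with the temperature anomaly. Defaults were
chosen once to match a transitional oceanic/continental Central European
site; the amplitude makes the vegetation-period mean ≈ 13.9 °C.
Engineered drought years add a VP temperature offset and multiply VP
precipitation: two severe years (+3 °C, ×0.45–0.5 at positions 10 and
25 of the 26-year record) and two milder ones (+0.5 to +1.5 °C,
×0.7–0.85) — the severe pair is what the primary stress criteria should
recover; the milder pair mimics drought years that only SPEI-type
evidence flags.

**Forest.** Ring width = ageTrend(t) · exp(β·z_driver) ·
droughtMultiplier · exp(year effect) · exp(tree noise); each core
multiplies the tree signal by its own lognormal noise (sd 10 %).
Lognormal noise keeps widths positive and makes the drought multiplier
the analytic expectation of per-tree resistance. The age trend is
negative-exponential (3·e^(−t/15) + 3 mm with 14 rings before the record
starts — trees already past their juvenile peak, as in a ~40-year-old
stand). The shared year effect (sd 0.2) stands for site weather not
captured by the driver, so species simulated on the same site share one
realisation (`year_effect_seed`); drawing it independently per species
would add between-species noise no single site exhibits. β = 0.165 by
default, set analytically so the chronology-level true correlation with
the driver is ≈ 0.6:
r = β/√(β² + sd_year² + var_drought + sd_tree²/n_trees); the realised
mean full-sample r across simulated studies is 0.58. Default species:
cedar-like (27 trees, February precipitation driver, mild drought
multipliers), spruce-like (17 trees, June driver, severe multipliers),
pine-like (13 trees, July driver, intermediate).

**What the generator does not emulate.** Growth persistence: the paper's
kind of biological carryover (raw-chronology Ar1 ≈ 0.5–0.6) is absent —
year effects are i.i.d. — so Ar1 on synthetic chronologies is near zero
and the generator cannot validate Ar1 magnitudes, only the estimator's
arithmetic (which hand oracles cover). Likewise no cambial phenology, no
cross-dating errors, no missing rings, and precipitation occurrence has
no day-to-day memory. Passing recovery tests therefore show the
*machinery* extracts programmed signals at realistic noise levels, not
that real forests behave like the generator.

**Single-event ratio noise.** With the default year-effect sd 0.2, a
single-event median Rs carries ~30 % multiplicative spread from the
shared year effect alone (e.g. one default-seed study realises
median Rs(2003) = 2.0 where 0.75 is programmed, because
η(2003) − η(2002) happened to be +0.82). This is the very motivation for
two-year windows and for medians across events; the isolated
drought-multiplier recovery check (low-noise configuration) recovers the
programmed multiplier within ±0.1.

## Numerical and design choices

- Percentiles everywhere: linear interpolation between order statistics.
- Bootstrap: percentile CI (not BCa); reported r is the full-sample
  coefficient; per-cell seeds spawned from one `SeedSequence`.
- The "top-|r| cell equals the driver cell" form of driver recovery is
  *not* asserted: with ~75 correlated cells, rain-day counts and SPEI of
  the driver's month are collinear with its precipitation sum (true
  r ≈ 0.5 against the chronology) and outrank it by sampling noise in
  roughly a third of runs at n = 26. The asserted recovery criteria are
  (a) the driver cell significant with the correct sign and (b) the
  driver month top among the driver variable's columns.
- RWL I/O: Tucson decadal format, 0.01 mm units, 999 terminator (−9999
  accepted for 0.001 mm files); widths are rounded to 0.01 mm on write,
  so a write/read round trip is identity at measurement precision.
- All pipeline randomness flows from one top-level seed recorded, with
  every parameter, in `run_log.json`.

## Known limitations

- Thornthwaite PET is temperature-based and underestimates PET in windy
  or advective conditions; the SPEI here inherits that.
- No cross-dating or dating-quality checks: input series are assumed
  correctly dated.
- The stress-year detector's "auto" event list uses both-primary-criteria
  or VP SPEI3 < −1; milder composite definitions require passing events
  explicitly.
- Only ratio (not difference) detrending indices and only the one spline
  family are provided.
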