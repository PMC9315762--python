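# Methods

This note records the models, numerical choices and open design decisions
behind `dendroseason`, in the spirit of a statistical-software methods
appendix. Problem sizes quoted below are the defaults used by the test suite
and `scripts/acceptance.py`.

## 1. The zero-growth decomposition

Stem radius from a point dendrometer mixes irreversible xylem growth with
reversible water-storage dynamics. The zero-growth (ZG) assumption — no
growth while the stem is below its precedent maximum — gives the exact
decomposition `r_t = M_t − TWD_t` with `M_t` the running maximum and
`TWD_t ≥ 0` the tree water deficit. Its key practical virtues for cold-climate
conifers are that (a) GRO increments cumulate to annual growth without the
overestimation that cycle-counting approaches suffer (every re-expansion
after shrinkage would otherwise be counted as growth), and (b) growth onset
can be dated against the *previous year's* maximum, which is robust to the
spring rehydration phase that fools continuous-curve fits.

Implementation notes:

- The running maximum is carried across calendar years within a tree's whole
  record; onset dating requires that cross-year state.
- Missing steps (NaN on the grid) neither reset nor advance the running
  maximum; TWD and increments are undefined there.
- Correctness is checked property-based (conservation
  `M_T − r_0 = Σ GRO_t`, exact reconstruction) and against a brute-force
  oracle that rescans the full prefix at every step, on series of 10⁴ points.

## 2. Season metrics and the tolerance mechanism

For calendar year *y*: `prev_max` = maximum radius over year *y−1*,
`curr_max` = maximum over year *y*, `G = curr_max − prev_max`. At tolerance
`q` (`tol_seas`, default 0.05, alternatives 0.10 and 0.20), onset/cessation
are the first observations reaching `prev_max + qG` and `prev_max + (1−q)G`.
First-crossing and first-occurrence ties always resolve to the earliest
timestamp; DOY is the calendar day (1-based) of the crossing timestamp.

The tolerance exists because the year's maximum hinges on a single
high-resolution observation on the asymptotic late-season curve; small
erratic fluctuations there move the dated cessation a lot. Raising `q`
avoids the flat tail: in the 50-seed study the SD of recovered cessation
falls 0.63 → 0.39 → 0.30 days as `q` goes 0.05 → 0.10 → 0.20 (identical
configuration across trees, so the spread is noise-driven). Onset is barely
affected, because spring growth is steep.

Choices that were genuinely open:

- **Total growth** defaults to the *threshold span* (radius at the cessation
  crossing minus radius at the onset crossing, ≈ (1−2q)·G); a `max_to_max`
  mode reporting G is available. Duration and rate at tolerance `q` pair the
  onset and cessation at the *same* `q`; headline tables use the 5% onset.
- **Validity**: a season needs a previous reference year, net growth
  `G > min_annual_growth_um` (default 30 µm ≈ 10× sensor noise SD — a purely
  positive-G rule would let a dead tree's noise-level maximum excursions
  create spurious "seasons"), no missing run longer than
  `season_break_days` (default 30 d; an unjoinable record cannot anchor the
  two crossings), and at least half the year observed. Invalid seasons carry
  reason codes (`no_reference_year`, `no_net_growth`, `sensor_break`,
  `insufficient_coverage`) so exclusion accounting is explicit.
- Report tables aggregate by simple means over the valid tree-seasons in
  each treatment × year cell; the "mean" column is the mean of those yearly
  cells.

## 3. Cleaning

Raw series are snapped to an exact 15-min grid (nearest observation within
half an interval; colliding observations are an error). Missing runs of at
most `max_gap_steps = 2` (i.e. gaps shorter than 3 steps) are linearly
interpolated and flagged; longer runs stay missing. Frost periods —
temperature strictly below `frost_temp_c = 5 °C`, padded by
`frost_pad_steps = 2` on each side — are flagged and exempted from spike
removal, because frost shrinkage is real signal.

Artifact detection works on first differences against a robust scale:
1.4826 × the median absolute deviation of the day's differences (per
calendar day; global fallback; floored at 0.1 µm so noise-free signals are
not flagged). A deviation beyond `tol_out = 10` × scale that is immediately
reversed is a single-point spike → removed and re-interpolated. A deviation
beyond `tol_jump = 50` × scale without reversal is a sensor
readjustment/replacement shift → the offset *in excess of the locally
expected difference* is subtracted from all subsequent values, preserving
every non-artifact difference exactly. The defaults were fixed by an
inject-and-recover study (a +500 µm jump and 2-step gaps shift season
metrics by ≤ 1 day and < 1% growth). The irreducible error of a jump
correction is the unknown sensor noise at the jump step itself (a few noise
SDs). In place of a manual visual-validation pass, the stage refuses to
proceed when more than 5% of points would be altered. The full cleaning
pipeline is idempotent.

## 4. The synthetic generator

The generator emulates the statistical structure of a 12-year soil-warming
experiment on slow-growing boreal conifers so that every downstream stage
has a recoverable oracle. Per tree and calendar year the noise-free signal is

```
r(t) = baseline + growth(t) − diurnal(t) − deficit(t)
```

- **Growth**: a Gompertz curve per year, renormalized to rise from exactly 0
  at Jan 1 to exactly the year's annual increment at Dec 31, with shape
  parameters solved (scipy `fsolve`, closed-form initial guess) so the 5%
  and 95% completion fractions fall exactly at the configured onset and
  cessation DOYs (taken as attained at midday). Default annual growth
  1160 µm, onset DOY 152, cessation DOY 244. The asymptotic Gompertz tail
  mirrors the late-season flattening that motivates the tolerance mechanism.
- **Diurnal cycle**: mean-zero cosine, peak-to-peak `diurnal_amplitude_um`
  (default 30 µm; no measured value was available, and tens of µm is
  typical of slow-growing conifers), maximal contraction mid-afternoon,
  period exactly `steps_per_day`. Because the previous year's maximum rides
  the same nightly bulge as the current signal, the mean-zero convention
  leaves threshold crossings unbiased.
- **Winter dehydration**: a smoothstep ramp to `winter_shrinkage_um`
  (default 800 µm, on the order of the annual increment, as reported for
  black spruce in comparable climates) starting `shrink_lag_days = 15` after
  cessation over `shrink_ramp_days = 30`, held through winter, recovered to
  exactly zero across the spring rehydration window (DOY 95–135). The first
  simulated year starts fully dehydrated. A rehydration window that could
  overlap the onset window is rejected — ground truth would be ambiguous.
- **Noise/artifacts**: Gaussian noise (default SD 3 µm, of the order of a
  potentiometer dendrometer's resolution), gaps as absent rows, jumps as
  step offsets. One `numpy` Generator seeded from `seed` fixes everything
  bit-for-bit.
- **Temperature**: annual sinusoid (mean 2 °C, amplitude 16 °C, peak
  mid-July) plus a small diurnal cycle and noise; the heated variant is
  offset +4 °C while the seasonal component is above freezing (emulating
  warming cables run from snowmelt to the first autumn frosts).
- **Dead-tree mode**: from a given year, zero growth plus a 150 µm yr⁻¹
  desiccation decline. The decline is deliberately larger than the previous
  living year's hidden late-season tail (below), so dead years always fail
  the net-growth validity gate — the mode exists to exercise the "no valid
  season" path deterministically.

**Configured vs realized truth.** Winter shrinkage begins before the growth
curve's slow tail is complete, so the last ~2–3% of the annual increment
accrues *below* the running maximum and only surfaces the following spring.
Realized threshold crossings therefore sit a few days off the configured
DOYs (and exactly on them when shrinkage is zero). Every simulated tree
carries both: `truth` records the realized per-year onset/cessation/growth,
computed from the noise-free signal with plain numpy (independent of the
phenology module), alongside the configured values. Recovery studies compare
extraction against realized truth — they measure the pipeline's noise and
cleaning error, not the simulator's internal geometry. In the 50-seed study
(3-year trees, default noise) the median absolute errors are 1 day (onset),
0 days (cessation) and ~0.1% (annual growth).

**Experiments.** `simulate_experiment` draws per-year (shared across trees),
per-tree and residual random effects for onset (SDs 5/3/3 d), cessation
(14/6/8 d) and log growth (0.25/0.12/0.10), matched once to the spread of
the published yearly means (growth year-to-year range ≈ 0.57–1.36× the mean,
cessation range ≈ ±30 d). Heated trees get `cessation_shift_days = −8` and
growth scaled by `rate_multiplier × duration_ratio = 1.18 × dur_h/dur_c`, so
the rate contrast is the multiplier and the total-growth contrast ≈ +9%.
One burn-in calendar year precedes the measurable seasons so the first
season has a reference maximum. Drawn onsets are clipped at rehydration end
+ 6 d and cessations to [onset + 40, 300]; clipping plus the smaller hidden
tail of the steeper (shorter) heated season attenuate the realized cessation
shift to ≈ −6 to −7 days for a configured −8.
`simulate_metrics_panel` draws the same per-tree-year random-effects
structure directly at the season-metrics level, for Monte Carlo studies of
the statistical layer where simulating thousands of 15-min series would be
pointless.

The generator does *not* emulate: drought-induced mid-season shrinkage,
autocorrelated sensor noise, temperature-dependent diurnal amplitude, or
partial first/last years. Passing tests therefore demonstrate correctness of
the processing chain under realistic signal structure, not performance on
every pathology of field data.

## 5. Robust statistics

`trimmed_mean(x, γ)` removes the ⌊γn⌋ smallest and largest values (scipy's
convention). The split-plot ANOVA on trimmed means follows the Wilcox
between-by-within construction: per treatment group, the vector of yearly
trimmed means with covariance estimated as `(n−1) S_w / (h(h−1))` (winsorized
covariance `S_w`, effective size `h = n − 2⌊γn⌋`), combined into a
Johansen-type quadratic statistic with a Welch-style df approximation, for
the treatment, year and interaction contrasts. Default trim 0.2 (the
convention of the robust-ANOVA literature; the analysis it reproduces states
no value). Significance stars use the published thresholds * < 0.1,
** < 0.01, *** < 0.001.

Verification: with a single within level the treatment test reduces
*exactly* to Welch's t² (trim 0) and to the Yuen trimmed t² (trim 0.2), both
checked against scipy to 12 digits; on large balanced homoscedastic panels
the untrimmed between-groups test tracks the classical split-plot F. A
degenerate all-identical panel returns statistic 0, p = 1. Subjects with
missing years are dropped (complete-case) with a warning.

Numerical caveats: when the number of within levels approaches or exceeds
the per-group subject count (e.g. 12 years, 6 trees) the winsorized
covariance blocks are rank-deficient and the year/interaction contrast
matrix `C V Cᵀ` is singular; the solver falls back to a pseudo-inverse and
those two tests should be read qualitatively. The 1-df treatment test is
unaffected. Under the generator's null (no treatment effect, 6+6 trees,
12 years, 1000 replicates) the treatment test rejects at the 0.05 level at a
rate of ≈ 0.028 on the growth-rate metric (0.026–0.046 across metrics;
≈ 0.031 even for iid normal panels): the trimmed split-plot test is known to
run mildly conservative at these group sizes, erring on the safe side.
Power against the default treatment effects (rate ×1.18) at these sample
sizes is moderate (≈ 0.4–0.5 at the 0.1 level).

Spearman correlations use average ranks for ties and the t-approximation
p-value (scipy), cross-checked against a brute-force average-rank
computation on small tied vectors.

## 6. Published-table arithmetic

`src/dendroseason/data/table1_means.csv` transcribes the published
treatment × year mean metrics (plus the 80%/90%-completion overall cessation
means, published only as headline values). `verify_table_arithmetic`
recomputes: overall onset/cessation/duration as means of the 12 yearly
overall values (151.9, 245.2, 93.2), and the heated-vs-control contrasts
from the published Means column — which, because tree counts are unbalanced
across years, is *not* the mean of the printed yearly means: rate
(15.0 − 12.7)/12.7 = +18.1%, total growth (1216 − 1115)/1115 = +9.1%,
duration 96 − 88 = 8 days, and the onset-to-80%-completion interval
201 − 151.9 ≈ 49 days.

## 7. Problem sizes and determinism

The test suite runs in about a minute on one CPU: 50 recovery seeds ×
3-year trees, 1000 null ANOVA replicates at panel level, one full 6+6 × 12-yr
pipeline, property tests with seeded/derandomized hypothesis profiles.
`scripts/acceptance.py` (~1 min) derives every stage's seed from `--seed`;
two runs with the same seed produce identical JSON.
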