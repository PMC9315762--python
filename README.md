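# dendroseason

Seasonal radial-growth phenology of trees from high-resolution point-dendrometer
records, using the **zero-growth (ZG) concept**.

Point dendrometers track stem radius continuously (here: 15-min resolution,
µm precision), but the irreversible growth signal is confounded with
reversible water-driven swelling and shrinkage — diurnal
contraction/expansion cycles, drought shrinkage, and months-long winter
dehydration in cold climates. Under the ZG assumption no growth occurs while
the stem is below its precedent maximum radius, so the radius series *r_t*
decomposes exactly into

```
M_t   = max(M_{t-1}, r_t)        running maximum
GRO_t = M_t - M_{t-1}  >= 0      irreversible growth increment
TWD_t = M_t - r_t      >= 0      tree water deficit
```

With *prev_max* the maximum radius of the previous calendar year and
*G = curr_max − prev_max* the annual growth, season metrics at a tolerance
fraction *q* (default 5%) are:

- **onset**: first DOY with `r >= prev_max + q G`
- **cessation**: first DOY with `r >= prev_max + (1−q) G`
- **duration** = cessation − onset; **total growth** = radius span between the
  two crossings; **rate** = total growth / duration (µm day⁻¹).

The package is aimed at tree ecophysiologists analysing dendrometer networks
in cold (boreal) environments, where winter dehydration makes curve-fitting
approaches unreliable. It provides:

- `dendroseason.synthetic` — a multi-year 15-min stem-radius + temperature
  simulator with known ground truth (Gompertz seasonal growth with exact 5%/95%
  completion days, mean-zero diurnal cycle, net-zero winter
  dehydration/rehydration, noise, gaps, sensor jumps, soil-warming treatment
  effects, dead-tree mode);
- `dendroseason.preprocess` — cleaning: grid alignment, linear filling of
  gaps shorter than 3 steps, frost flagging from a paired temperature record,
  robust (MAD-based) spike removal and sensor-jump correction
  (`tol_out` / `tol_jump`);
- `dendroseason.zero_growth` — the exact GRO/TWD decomposition;
- `dendroseason.phenology` — per tree-year season metrics with the `tol_seas`
  tolerance mechanism and validity/reason accounting;
- `dendroseason.robust_stats` — trimmed means, the between-subjects
  (treatment) × within-subjects (year) split-plot ANOVA on 20%-trimmed means
  (Wilcox/Johansen-type, Welch-style df), Spearman rank correlations;
- `dendroseason.pipeline` / a `dendroseason` CLI — orchestration and
  treatment × year report tables.

## Worked example

```python
from dendroseason import SimulationConfig, simulate_tree, clean, decompose
from dendroseason.phenology import season_metrics

tree = simulate_tree(SimulationConfig(seed=7, n_years=3))   # 2010-2012
cleaned = clean(tree.radius_series, tree.temperature_series)
z = decompose(cleaned)
sm = season_metrics(z, 2011)
print(sm[sm.q == 0.05][["onset_doy", "cessation_doy", "duration_days",
                        "total_growth_um", "rate_um_per_day"]])
print(tree.truth[tree.truth.year == 2011][["onset_true", "cessation_true"]])
```

prints

```
   onset_doy  cessation_doy  duration_days  total_growth_um  rate_um_per_day
0        148            234             86      1043.880832        12.138149
   onset_true  cessation_true
0         147             235
```

i.e. the extracted growth onset (day 148) and cessation (day 234) recover the
simulated tree's realized ground truth to within a day, the season lasted 86
days, and the tree added ~1.04 mm of radius between the 5% and 95% completion
thresholds at ~12.1 µm per day.

The same chain from the shell:

```sh
dendroseason simulate --seed 7 --n-control 6 --n-heated 6 --years 12 --out-dir sim/
dendroseason clean --in sim/C01_radius.csv --temp sim/C01_temp.csv --out C01_clean.csv
dendroseason decompose --in C01_clean.csv --out C01_zg.csv
dendroseason phenology --in C01_clean.csv --out C01_metrics.csv
dendroseason report --seed 7 --out-dir report/
```

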