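# tvdlnm

Time-varying distributed lag non-linear models (tv-DLNM) for quantifying
long-term change — *adaptation* — in the temperature–mortality
association of a city from daily time series.

Heat and cold kill with a delay: today's temperature affects mortality for
up to three weeks, non-linearly, with the highest risks at the extremes of
the local temperature distribution.  DLNMs capture this with a tensor
product ("crossbasis") of a natural cubic spline in temperature and a
natural cubic spline in lag, inside a quasi-Poisson regression of daily
death counts adjusted for season, long-term trend, day of week, holidays,
humidity and PM10:

    log E[Y_t] = α + cb(temp)_t + dow + holiday + PM10_{lag0–2}
               + ns(RH_{lag0–2}, 3) + ns(time, 10 df/yr) + cb(temp)_t × s_t

The final interaction lets the whole exposure-lag-response surface drift
linearly over calendar time.  From one fit the package extracts, for every
year: the lag-cumulated relative risk (cRR) curve, the percentile-
constricted minimum mortality temperature (MMT) with parametric-bootstrap
empirical confidence intervals, and cRRs at the 1st/10th/90th/99th
percentile anchors re-centred at that year's MMT.  A multivariate Wald
test on the interaction block asks whether the surface changed at all, and
inverse-variance weighted regressions of the annual indicators on year (or
on annual temperature indicators) quantify the direction and pace of
adaptation.

The package is aimed at environmental-epidemiology analysts: the library
(`src/tvdlnm/`) carries every computation, the numbered scripts under
`analysis/` run the study end to end on a synthetic city, and a
`tvdlnm` CLI (`simulate`, `fit`, `indicators`, `trends`, `sensitivity`,
`report`) wraps the same functions for shell use.  Because the motivating
mortality microdata are access-restricted, a first-class synthetic
generator (`ScenarioTruth`, `simulate_city`) reproduces their statistical
structure — subtropical Southern-hemisphere seasonality around a ~19.6 °C
mean with cold-front winter tails, overdispersed counts (~600 deaths/day),
and a U-shaped lagged risk surface whose MMT drifts upward — with
closed-form ground truth for every indicator, so the whole pipeline is
testable against known answers.

## Worked example

```python
import numpy as np
from tvdlnm import (RunConfig, ScenarioTruth, annual_indicators,
                    assemble_design, fit_tv_model, simulate_city,
                    wald_interaction_test, wls_trend)

truth = ScenarioTruth()                      # MMT drifts +0.09 C/year
series, truth_mmt, _ = simulate_city(truth, n_years=19, seed=1)
cfg = RunConfig(seed=1, n_boot=300)

design = assemble_design(series, "all", cfg)
fit = fit_tv_model(design)
print(f"dispersion {fit.dispersion:.2f}")
print(f"Wald p = {wald_interaction_test(fit, design).p_value:.2e}")

rng = np.random.default_rng(1)
annual = [annual_indicators(fit, design, y, rng) for y in range(2000, 2019)]
first, last = annual[0], annual[-1]
print(f"MMT 2000: {first.mmt.mmt:.1f} C "
      f"({first.mmt.eci_low:.1f}; {first.mmt.eci_high:.1f})")
print(f"MMT 2018: {last.mmt.mmt:.1f} C "
      f"({last.mmt.eci_low:.1f}; {last.mmt.eci_high:.1f})")
trend = wls_trend([a.year for a in annual], [a.mmt.mmt for a in annual],
                  [max(a.mmt.se, 1e-6) for a in annual])
print(f"MMT trend: {trend.slope:+.3f} C/year (p = {trend.p_value:.1e})")
```

prints

```
dispersion 1.31
Wald p = 5.53e-06
MMT 2000: 20.6 C (20.1; 20.9)
MMT 2018: 22.3 C (21.7; 23.0)
MMT trend: +0.092 C/year (p = 9.1e-18)
```

The fit flags a significantly time-varying surface (Wald p ≪ 0.05), the
annual MMTs climb from 20.6 to 22.3 °C, and the weighted trend, +0.092
°C/year, recovers the generator's 0.09 °C/year drift.  The quasi-Poisson
dispersion 1.31 matches the generated variance/mean ratio of 1.3.

The same study as a script sequence:

```
python analysis/01_simulate.py      # climate + mortality summary
python analysis/02_fit_tvdlnm.py    # fits and Wald tests per stratum
python analysis/03_indicators.py    # annual MMT/cRR tables
python analysis/04_trends.py        # trend and coupling regressions
python analysis/05_sensitivity.py   # qAIC grid over parametrizations
```

Each driver prints what it found and writes compact tables under
`results/`.

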