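# valvometry

Analysis of bivalve gaping behavior from Hall-effect valvometer logs:
sensor quality control, daily-z-score normalization, closure-event
("valve-clap") detection, environmental covariate models, and Morlet
wavelet rhythm analysis — plus a simulator that generates the whole study
with known ground truth.

The package targets the common biologging setup for photosymbiotic giant
clams (*Tridacna*): a magnet on one valve, a Hall sensor on the other, an
Arduino logging millivolts every 5 s, and co-deployed loggers for PAR, pH,
dissolved oxygen, temperature and chlorophyll-a / phycoerythrin
fluorescence. It is for behavioral ecologists who want the full chain from
raw voltage to statements like "closure frequency lags chlorophyll blooms
by four days" with every step reproducible and testable.

## The analysis

Raw voltages drift day to day, so each local calendar day is standardized
(sample SD):

    z_t = (mV_t − μ_day) / SD_day
    %closure_t = (z_t − z_daymin) / (z_daymax − z_daymin) × 100

Closure events are transient peaks in z: strict maxima of a centered
3-point moving window with prominence ≥ 1 daily SD, extending to the
half-prominence reopening on either side. Daily event counts are modeled
against daily-mean covariates with an additive model (penalized cubic
splines; ANOVA-for-parametric-effects table) and with the lead/lag
cross-correlation function r(k) = corr(x_t, y_{t+k}) under the classic
±1.96/√N bounds (positive lag = closure lags the covariate). Rhythms are
analyzed with the complex Morlet CWT (ω₀ = 6): time × period power with
AR(1)-surrogate significance and cone of influence, 24-h band
reconstruction and residual (ultradian) re-analysis, and wavelet coherence
with phase (0 = in phase, ±π = anti-phased). See `docs/methods.md` for
conventions and assumptions.

## Worked example

One command simulates a deployment and runs every stage:

```sh
valvometry run-all --seed 3 --n-days 60 --out runs/demo
```

which prints (abridged):

```
[simulate] 60 days, 3 clams
[qc] 0 flags
[gape] regimes:
                           n   mean     sd  median
clam   regime
...
pooled dark            75558  44.85   7.57   43.81
       low_light       94707  40.03   8.20   39.42
       bright          88893  10.81   8.88    9.32
[events] 2457 events, 41.0/day
[envstats] best positive CCF lag: 4 d (closure lagging chlorophyll)
[rhythms] wavelet power peaks at 24.3 h
run complete -> runs/demo
```

Read: the clams sit ~45% closed in dark hours versus ~11% when PAR exceeds
100 μmol photons/m²s; valve-claps arrive ~41/day pooled across three
clams, their daily frequency tracking chlorophyll with a 4-day delay; and
gape is dominated by a circadian (24 h) rhythm. On short records the lag
estimate is noisy — a 30-day run of the same seed puts it at 2 days — so
lag statements deserve the full deployment length. `runs/demo/` holds the
regime summary, the event table with durations, the daily count × covariate
table, the additive-model ANOVA, the CCF, and a wavelet power heatmap.

The same stages are available as a library:

```python
from valvometry import simulate, qc, io, gape, events, envstats, rhythms

ds = simulate.simulate_dataset(simulate.SimulationConfig(seed=3, n_days=8))
masked, report = qc.run_qc(ds.valve)
aligned = io.align(masked, list(ds.env.values()), valve_grid_s=60)
part = gape.light_partition(aligned.env["PAR"])
g = gape.percent_closure(gape.daily_zscore(aligned.valve[1], "auto", part))
wav = rhythms.cwt_power(g.pct_closure, seed=0)
print(wav.peak_period_h())   # 24.25
```

Real deployments enter through `io.read_valve_log` (tab-delimited
timestamp + mV columns) and `io.read_env_csv`, or the `valvometry ingest`
subcommand.

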