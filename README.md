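# ttherm

Activity and body-temperature analytics for giant-tortoise biologging.

Large ectotherms such as the Aldabra giant tortoise regulate activity and
body temperature against a fluctuating thermal environment. Field studies
of this question produce a characteristic bundle of data: shade and sun
temperature loggers at 15-min cadence, collar accelerometers recording a
36-reading voltage burst every 5 min, ingested loggers reporting core
(gut) temperature T_bc, and spot infrared readings on 21 body sites
(13 carapace scutes, 4 extremities, 4 skin folds). `ttherm` is a tested,
reusable pipeline for exactly this bundle, aimed at thermal ecologists and
zoo/conservation scientists who need the standard analyses without
re-deriving them:

- **Activity classification** — per-burst standard error, centered rolling
  mean, threshold rule (ties to active), assumed overnight inactivity.
- **Thermal optimum (T_a-opt)** — Gaussian KDE of air temperature
  conditioned on behavioural state, with a common Silverman bandwidth; the
  optimum range is the longest contiguous run of temperatures where the
  active-state density exceeds the inactive-state density.
- **Cosinor rhythms** — least-squares fit of
  `y = M + A·cos(2π(t − φ)/24)` via the linear basis {1, cos, sin}:
  mesor M, amplitude A, acrophase φ, and circular acrophase lags between
  series (core temperature trailing air temperature).
- **Daily thermal statistics** — per-day ΔT_bc and ΔT_air ranges, the
  ΔT_bc/ΔT_air quotient (thermal lability normalised by environmental
  forcing), heating/cooling slopes, Kendall τ-b with tie-corrected z, and
  Wilcoxon rank-sum tests (exact by enumeration at small n).
- **Activity GLM** — fixed-effects logistic regression of the binary state
  on year, day period, season, centered air temperature and interactions,
  fitted by IRLS with Fisher-information standard errors; ΔAIC comparison.
- **Comparative meta-analysis** — rank correlations of core range vs mass,
  core range vs air range, and the air-corrected quotient vs mass across
  published Testudinidae measurements.
- **Synthetic trials** — a generator producing complete trials
  (environment, bursts, core, surface) with the statistical structure the
  analyses assume, including first-order Newtonian heat exchange
  `dT_bc/dt = k(m)(T_op − T_bc)` with `k(m) = k0·m^(−1/3)`, so every stage
  is testable against closed forms without field data.

## Worked example

```python
import ttherm as tt

cfg = tt.SyntheticConfig(days=10, seed=7)          # warm-trial defaults
shade, sun = tt.simulate_environment(cfg)
states, bursts = tt.simulate_activity(shade, cfg)  # latent states + ACC bursts

st = tt.classify_states(bursts, window=3, threshold=5.0)
aligned = tt.align_series(st["state"], shade.data, max_gap_min=8)
res = tt.ThermalOptimum(aligned["value_b"], aligned["value_a"]).fit()
print(res.summary())
```

```
Thermal optimum (state-conditional KDE)
  n active / inactive : 841 / 1317
  bandwidth           : 0.534 degC
  T_a-opt range       : 26.9 - 31.0 degC
  mean T_air (active) : 29.2 degC (SD 1.6)
  quartiles (active)  : 27.9 - 30.6 degC
```

The recovered 26.9–31.0 °C interval is the generator's 26–31 °C activity
preference window seen through ten days of classification and KDE: the
temperatures at which the animal is more often active than inactive. The
body-temperature side of the pipeline:

```python
core = tt.simulate_core_temperature(shade, sun, states, tt.Individual("T01", 75.0), cfg)
fit = tt.Cosinor(core.data).fit()
print(fit.summary())
lag = tt.acrophase_lag(fit, tt.Cosinor(shade.data).fit())
print(f"core acrophase lag behind air: {lag:.2f} h")
```

```
Cosinor fit (period 24 h, n=960)
  mesor     :  28.920 degC
  amplitude :   2.453 degC
  acrophase : 17.13 h
  RSS       : 1232.783
core acrophase lag behind air: 2.57 h
```

A 75-kg body with exchange rate `k = k0·75^(−1/3) ≈ 0.24 h⁻¹` damps the
daily cycle and peaks about 2.6 h after the air — matching the first-order
closed form (amplitude ratio `1/√(1+(ω/k)²)`, lag `atan(ω/k)/ω`).

The same stages are available from the shell:

```sh
ttherm simulate --seed 7 --out trial/
ttherm classify --acc trial/acc_T01.csv --out cls/
ttherm optimum  --states cls/states.csv --env trial/env_shade.csv --out opt/
ttherm report   --trial-dir trial/ --out report/
```

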