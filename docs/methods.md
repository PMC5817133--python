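# Methods

This note documents the statistical procedures `ttherm` implements, the
assumptions behind its synthetic-trial generator, the defaults and why
they were chosen, and the limits of what the synthetic tests demonstrate.

## Data model and alignment

Timestamps are naive local clock times: each trial happens at a single
site, and logger exports carry local time. Environmental and core series
run at a nominal 15-min cadence, accelerometer epochs at 5 min. Gaps are
allowed and reported (count, longest) rather than filled. Series are kept
at full float precision in memory; the CSV writers format at 0.01 °C,
which exceeds logger accuracy (0.05–0.06 °C), so a write–read round trip
is exact.

Coupling the 5-min activity epochs to 15-min temperatures uses
nearest-neighbour pairing with a maximum gap of 8 min — half the coarser
cadence plus slack, so every epoch finds its natural partner and nothing
pairs across a real gap. `previous` and `interpolate` rules are available;
unmatched rows are dropped and counted, never interpolated silently.

Days are calendar days (midnight to midnight). Daily summaries require
75 % coverage of the expected samples before they are emitted, guarding
min/max statistics against partial days. Whether deployment windows
rather than calendar days were intended by any particular field protocol
is a choice the caller can revisit; calendar days are the default because
they need no extra metadata.

## Activity classification

Each 5-s burst yields 36 voltage readings. The per-burst statistic is the
standard error, sample SD divided by √36. Whether a given logger's
"burst SE" convention means SD or SD/√n only rescales the statistic by a
factor 6, which the threshold absorbs; both the statistic and the
threshold (default 5, raw voltage units) are parameters. The rolling mean
over bursts uses a centered window (default 3 bursts, truncated at the
series edges — the window length is a convention, not an estimate, and is
exposed as `window=`). The state rule is `rolling_se >= threshold`, with
ties resolving to active; epochs between 00:00 and 06:00 are forced
inactive, matching a recording design that assumes overnight rest.
Modelling (the GLM) further restricts epochs to 06:00–20:00 inclusive.

## Thermal optimum

Activity epochs paired with shade air temperature are split by state.
Each state gets a Gaussian kernel density on a shared grid (0.1 °C step,
spanning the data ± 3 bandwidths). The bandwidth is Silverman's rule per
state — `0.9·min(sd, IQR/1.34)·n^(−1/5)` — with the **larger** of the two
taken for both, so crossings of the curves reflect the data rather than
bandwidth asymmetry. The optimum range is the longest contiguous run of
grid points where the active density exceeds the inactive density; minor
crossing runs are reported separately rather than merged or hidden, and a
never-exceeding active density yields a flagged undefined result, not an
exception. Endpoints are bandwidth-sensitive at the 0.1–1 °C scale;
`bandwidth=` accepts an explicit value for sensitivity analyses. Summary
statistics of the active state (mean, SD with n−1, linearly interpolated
quartiles) are computed on the temperatures themselves, not the density.

Each epoch counts once; individuals are pooled without reweighting. With
per-individual series available, leave-one-out ranges are a two-line loop
over `ThermalOptimum`.

## Cosinor rhythms

The fixed-period cosinor is linear least squares on {1, cos ωt, sin ωt}
with ω = 2π/24 h⁻¹: amplitude `A = √(βc² + βs²)`, acrophase
`φ = atan2(βs, βc)/ω` wrapped to [0, 24). Period is fixed at 24 h — no
period scan, no multi-component fit. A constant series returns amplitude
0 with the acrophase flagged undefined. Acrophase lags are circular
signed differences mapped to (−12, +12] h, positive when the first series
peaks later.

Discretised day periods: the four activity periods are fixed clock
intervals (06:00–08:00, 08:15–13:30, 13:45–17:30, 17:45–20:00); interval
endpoints are inclusive and the 15-min seams between them belong to the
earlier period. The three thermoregulation periods are trial-specific and
derived, by default, from the turning points (minimum and maximum) of the
2-h-smoothed grand-mean daily core curve — an approximation, since the
original trial-specific turning points are a field-protocol detail; any
scheme can be supplied explicitly.

## Rank statistics

Kendall's τ-b is computed from the concordant–discordant excess S with
tie corrections in the denominator; z uses the tie-adjusted variance of S
and p is two-sided normal. All-tied variables yield a flagged undefined
result. The Wilcoxon rank-sum test uses midranks; for combined n ≤ 12 the
null distribution of the rank sum is enumerated exactly over all
assignments (ties handled exactly), otherwise the normal approximation
with continuity and tie correction applies. Two-sided p-values
throughout.

## Activity GLM

The activity model is a fixed-effects binomial GLM: intercept, year
dummies, period dummies (reference period I), season (Nov–Apr wet,
May–Oct dry; reference wet), centered air temperature, and
temperature-by-season and temperature-by-period products. Centering
before forming interactions keeps the IRLS iterations well-conditioned.
Factor dummies are built only for levels present in the retained epochs,
so the design never carries all-zero columns.

Fitting is IRLS to the logit-link MLE, with standard errors from the
inverse Fisher information; the log-likelihood path is retained and is
non-decreasing. Divergence (|β| > 50 on the standardized scale) raises a
separation error. The link is logit by default; a literal `link="log"`
variant exists for replicating analyses phrased with a log link, with the
caveat that log-link binomial fits require fitted probabilities below 1
and are clipped. Random effects for individual and day are deliberately
out of scope — fixed individual dummies are the offered substitute, and
AIC comparisons (`compare_models`) require identical response rows.

## Synthetic trial generator

The generator defines the study conditions the test suite runs under.

**Environment.** Shade temperature is a 24-h cosine plus day-level mesor
jitter plus AR(1) noise:
`shade(t) = mesor + jitter(day) + A·cos(ω(t − φ)) + ε(t)`, with defaults
mesor 29 °C, amplitude 3.25 °C (daily range 6.5 °C), acrophase 14.5 h,
day jitter SD 2 °C, AR(1) ρ = 0.6 at 15-min steps with stationary SD
0.5 °C. These reproduce a warm tropical-trial envelope: mean near 29 °C,
day-to-day wander of a few degrees, smooth within-day noise. The sun
series adds a deterministic half-sine radiative increment (peak 10 °C)
over 06:00–18:00 and equals shade at night, giving the observed pattern
of shared nightly minima and divergent daytime maxima.

**Activity.** P(active | t, T) = drive(hour) · window(T). The drive is a
two-Gaussian bimodal profile (morning peak 08:30 weight 1.0, afternoon
17:00 weight 0.6, width 2 h, zero before 06:00). The window is 1 inside
the 26–31 °C preference band with logistic shoulders of 1 °C scale —
activity collapses within a few degrees above the band, the
steep-decline shape reported for tortoises near 31–32 °C. States persist
over 15-min bouts (one Bernoulli draw per 3 epochs at the bout-mean
probability): behaviour is not i.i.d. at 5-min resolution, and without
persistence a centered rolling window necessarily misclassifies isolated
single-epoch bouts. Bursts are 36 draws around a constant level with SD
60 (active) or 6 (inactive) — SE ≈ 10 vs ≈ 1 against the threshold of 5,
a clean 5σ-style separation; only dispersion distinguishes states because
only dispersion enters the classifier.

**Core temperature.** First-order Newtonian heat exchange
`dT_bc/dt = k(m)(T_op − T_bc)`, `k(m) = k0·(m/kg)^(−1/3)`, k0 = 1 h⁻¹.
This is a stand-in mechanism, not a biophysical claim: it is the simplest
model producing the observed phenomenology (core lagging and damping the
environmental cycle, heavier animals more damped), and it has closed
forms — steady-state amplitude ratio `1/√(1+(ω/k)²)` and lag
`atan(ω/k)/ω` — that the simulation must match, which pins the
integrator. The 1/3 mass exponent is the surface-to-volume heuristic and
is configurable, since the field evidence is that mass effects are
context-dependent rather than law-like. k0 = 1 h⁻¹ puts study-mass
animals (40–160 kg) at amplitude ratios ≈ 0.55–0.7 and lags ≈ 2.5–3.5 h,
the right first-order magnitude for daily core ranges roughly half the
air range. Integration uses the exact exponential update per 15-min step
with the forcing held at its step midpoint; a left-endpoint convention
would introduce a spurious half-step (0.125 h) phase lag. Operative
forcing is `f·sun + (1−f)·shade` during active epochs (basking fraction
f = 0.3) and shade otherwise.

**Surface temperatures.** Region series are convex mixtures
`w·T_env + (1−w)·T_core` with weights 0.8 (carapace), 0.5 (extremities),
0.2 (skin folds) plus 0.3 °C spot noise, sampled at 2-h cadence for 3
days over the 21-site scheme. Mixtures of this form automatically yield
the observed orderings: daily range carapace > extremities > skin folds >
core, and turning points environment → carapace → extremities → skin
folds → core.

**Comparative cohort.** The generator can also emit a literature-style
cohort of 22 daily-range measurements across 6 species in 4 genera (7
flagged as estimated mass). Air ranges trend down with species mass
(1.5 °C per decade of mass) — emulating the sampling reality that small
continental species are measured in more variable climates than large
island species — while the damping applied to produce core ranges uses a
deliberately mild exponent (0.12) plus 0.7 °C noise. The cohort therefore
shows a clear negative core-range-vs-mass correlation that weakens, but
does not vanish, once the air range is divided out — the qualitative
structure the comparative analysis is designed to detect. The shipped
`data/testudinidae_synthetic.csv` is exactly such a cohort (seed 42) and
is synthetic; users supply their own collated table for real analyses.

## What the synthetic tests do and do not show

Passing tests establish that each stage computes what it claims
(classification equals brute force; cosinor, KDE, IRLS and rank
statistics match independent oracles; the integrator matches the ODE
closed form) and that the full pipeline recovers known generator
parameters — the 26–31 °C window to ±1 °C on both endpoints in ≥ 18 of
20 seeds at 20 days × 8 individuals. They do not establish that real
tortoise data satisfy the generator's assumptions: real bursts have
waveform structure (gravity axes, gait harmonics) rather than pure
dispersion differences; real basking behaviour is state-dependent in ways
a fixed basking fraction ignores; heat exchange in a real body is not a
single first-order compartment; and real activity drives are
weather-dependent, not a fixed two-peak function. Endpoint estimates of
the optimum range inherit KDE bandwidth sensitivity of a few tenths of a
degree.

## Problem sizes and numerical choices

Default test problem sizes — 4–20 synthetic days, 4–8 individuals,
n = 5000 for GLM recovery — were chosen as the smallest sizes at which
the estimators' sampling noise is comfortably inside the stated
tolerances. Tolerances: 1e-8 for noiseless cosinor recovery, 1e-6 against
the Newton oracle, 1 % / 0.1 h for the heat-exchange closed form, ±1 °C
for KDE endpoint recovery (the bandwidth scale). Degenerate inputs
resolve to flags, not exceptions, wherever a result object can carry
them: undefined acrophase (constant series), undefined optimum range
(active never exceeds inactive), undefined τ (all ties), undefined daily
quotient (zero air range). Ties at the classification threshold go to
active; the longest crossing run wins with earlier-run tie-break.
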