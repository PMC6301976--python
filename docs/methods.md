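# Methods

## Model structure

reefcast simulates percent coral cover *P(t)* as a hybrid system: smooth
logistic growth between acute thermal-stress events, and exponential decay
during them.

**Inter-event growth.**  dP/dt = rP(1 − P/K) − γT(t)P.  The γT term is a
per-capita mortality/suppression rate proportional to background
sea-surface temperature; it shifts the positive equilibrium from K down to
P₂ = K(1 − γT/r).  When γT/r reaches 1 the positive equilibrium collides
with extinction (transcritical bifurcation): persistence is impossible no
matter the starting cover.  Because T enters in °C (not as an anomaly), γ
values are small (10⁻³-scale) and only meaningful jointly with T; we adopt
the published working values γ = 0.001 (base) and 0.005 (high
susceptibility) rather than re-deriving a γ scale.

**Event mortality.**  During an event starting at t_k with intensity ε,
P(t) = P(t_k)·exp(−ε³(t − t_k)).  The exponent uses *elapsed* time in
years: an absolute-calendar-time exponent would make identical events more
lethal in later years, which is dimensionally indefensible.  A consequence
worth stating plainly: a 4-week event at ε = 3 removes ~87% of cover, and
at ε = 8 essentially all of it (factor ≈ e⁻³⁹).  Events with ε = 0 are
treated as non-events (growth continues); a literal reading would freeze
cover for the event's duration, which has no biological interpretation for
a zero-intensity anomaly.

**Temperature.**  T(t) = I_ave(a₁cos 2π(t−t₀) + a₂sin 2π(t−t₀)) + λ(t−t₀)
+ a₃.  The seasonal argument is 2π per year (a raw radian argument would
give a ~6.3-year "season").  I_ave = 45 throughout.  The packaged scenario
coefficient sets (modern, RCP 4.5/6.0/8.5) use a trend origin at calendar
year zero: that is the only origin under which their negative a₃
intercepts produce tropical SSTs (25.3–26.1 °C across scenarios in 2005,
rising by λ·95 yr to 2100).  User-fitted models default to t₀ = 2005.  The
published λ values (0.015/0.021/0.039 °C yr⁻¹) are adopted as given; they
are not exactly re-derivable from the stated 2100 warming targets with any
single baseline year.

**Event schedules.**  Start-to-start gaps are Poisson(6)-distributed years
rejected outside [3, 9] — the historical range of El Niño return periods
for weak-through-strong events; very strong events (≥2 °C anomalies,
~22-year return) are too rare to schedule over a single century and are
excluded.  The high-frequency variant uses [3, 6] with mean 4.5.  Durations
are gamma(shape 2, scale 2) weeks rejected outside [2, 8]; the shape/scale
pair is our choice (the source range 2–8 weeks is stated without a
distribution) and puts most mass at mid-range durations (~4 weeks).
Events start at mid-summer (phase 0.5 within the year), configurable.

**Integration.**  Fixed-step classical RK4 at dt = 1/52 yr, so event
windows align with the weekly grid.  A step partially covered by an event
applies the exact exponential decay over the covered fraction and RK4
growth over the remainder; halving dt therefore changes trajectories only
at RK4 order (verified ≤1e-5 % cover).  Against the constant-temperature
closed form the solver agrees to ~1e-11 relative over 30 years.  Cover is
clamped to [p_floor, 100] with p_floor = 0.1% by default: a strictly
absorbing zero would make any deep-kill event permanent, whereas real
reefs receive external larval supply.  Set p_floor = 0 for a closed
population.  When the intrinsic rate is stochastic, r is redrawn from the
fitted Beta distribution at calendar-year boundaries (not per dt, which
would make dynamics resolution-dependent; a per-step mode exists for
comparison).

## ENSO classification

An El Niño event is five or more consecutive overlapping 3-month seasons
with ONI anomaly ≥ 0.5 °C (threshold inclusive); strength classes by peak
anomaly are weak [0.5, 1.0), moderate [1.0, 1.5), strong [1.5, 2.0), very
strong ≥ 2.0 — boundaries closed on the left.  Return-period statistics use
differences of event starting *calendar years* (whole years), matching the
convention under which historical medians are integers.

## Bayesian inversion

Observed annual cover y_t = μ(t; r, K, P₀) + e_t with μ the logistic
solution and AR(1) residuals e_t = ρe_{t−1} + ν_t, ν_t ~ N(0, σ²), and a
stationary initial residual e₀ ~ N(0, σ²/(1−ρ²)).  Priors: r ~ U(0, 1),
K ~ U(0, 100), P₀ ~ U(0, K), ρ ~ U(−1, 1), σ ~ half-Normal(10).  P₀ is a
free parameter: pinning it to the first (noisy) observation anchors the
whole curve to one error realization and measurably degrades interval
calibration for r and K (in our 20-replicate recovery simulation, coverage
of the 95% intervals fell to ~75–85%; with P₀ free it is 100%).

Sampling uses emcee's affine-invariant ensemble (32 walkers, 5000 steps,
50% burn-in by default — 80,000 retained draws), seeded and bit-for-bit
reproducible.  R-hat is computed over walker pseudo-chains via arviz and
fits are flagged (warning + `converged=False`) above 1.1.  Posterior r
draws are condensed to a Beta(α, β) by maximum likelihood (moment-matching
start and fallback); β mean α/(α+β) is the scalar recovery rate quoted for
a site.

γ is estimated afterwards from the constant-temperature closed form with K
and T fixed and r integrated over the supplied posterior draws: a 1-D grid
posterior on γ ∈ [0, max(r)/T] (so the net rate r − γT can change sign only
inside the support), with σ profiled at its conditional maximum and draws
taken by inverse-CDF sampling.  This is deterministic up to quadrature on a
401-point grid.

## Ensembles and summaries

Each ensemble run gets a generator spawned deterministically from the
master seed and draws its own schedule and yearly r values, so the whole
ensemble is a pure function of its `ScenarioConfig`.  Summaries: per-year
cover quantiles (2.5/25/50/75/97.5%, type-7 linear interpolation for
bit-exactness), the terminal-2100 distribution with its 95% equal-tailed
interval, a year × 2%-cover-bin histogram for heat-map rendering, and a
threshold-based modality classification: collapsed mass below 10% cover,
recovered mass above 25%, "bimodal" when each mode holds ≥10% of runs, a
single label at ≥90%, otherwise "intermediate".  Fixed thresholds were
chosen over a statistical dip test for transparency and testability; the
10% threshold mirrors the observation that populations hovering below
~10% cover rarely recover.

## Scenario intensity calibration

The extreme-event coefficient ε is the model's least-constrained knob: it
is defined only through f(ε) = −ε³ and has no stated mapping to measured
anomaly °C.  Under the elapsed-time mortality convention used here, the
regime ladder of the system (scanned over ε at 400-run scale, γ = 0.001,
RCP 6.0 trend, southern-Japan Beta r draws) is: full recovery for ε ≲ 1.8,
an intermediate band, a genuinely bimodal recovery-or-collapse band at
ε ≈ 2.4–2.6, and near-certain collapse for ε ≳ 2.8.  The packaged presets
place each pathway in the regime it is expected to produce: RCP 4.5 uses
ε = 1.5 (low-magnitude anomalies; ensembles hold near carrying capacity),
RCP 6.0 uses ε = 2.5 (the transition band; bimodal terminal
distributions), and the RCP 8.5 stress presets use ε = 8 with γ = 0.005
(every event razes cover to the floor; with 3–6-year intervals the
population cannot recover, terminal medians below 1%).  Note that under a
different event time base (e.g. exponents accumulated per week), the same
regime ladder appears at larger ε values; the ladder, not the absolute ε
scale, is the robust prediction.

## Synthetic data

`generate_synthetic_cover` emulates observed post-bleaching recovery
records: a logistic path, one multiplicative bleaching drop (e.g. survival
fraction 0.15 at the 1998-style event), AR(1) Gaussian observation noise,
clamped to (0.1, 100).  It does not emulate observer error structure
beyond AR(1), multi-taxon covariance, or depth/habitat stratification —
so passing recovery tests demonstrates statistical calibration of the
estimator under the model's own assumptions, not robustness to real survey
artefacts.  `generate_synthetic_oni` builds anomaly series whose events
are exact by construction: triangular warm pulses reaching a specified
peak over a specified season range, on a noise baseline truncated below
0.4 °C so noise can neither create nor extend an event.  The historical
NOAA ONI table (1950–2016) is not shipped; the classifier accepts the
NOAA wide layout directly, and its documented reference return periods on
that record are mean gaps 2.7 (all events), 5.4 (≥moderate), 10.8
(≥strong) and 21.7 years (very strong; median 18).

## Problem sizes and numerical choices

Default test and demonstration scales: 300–1000 ensemble runs (quantile
summaries stabilize well below 300), 10,000 schedules for sampler checks,
5000-step/32-walker MCMC, 50,000 draws for Beta recovery checks.  Schedule
gap statistics are compared against the exactly enumerated truncated
Poisson using the *first* start-to-start gap of each schedule: interior
gaps are horizon-censored (a gap that would overshoot the simulation end
is discarded, an inspection-paradox bias of order 0.03 years at a 95-year
horizon), while the first gap is a clean draw.  Rejection samplers cap at
10,000 tries and configurations whose mean lies outside the truncation
bounds are rejected at construction.  Degenerate closed-form cases
(r = γT) use the analytic limit P₀/((r/K)P₀t + 1).

## Known limitations

Single-taxon, spatially implicit, no Allee effect below the floor, no
adaptation or thermal-tolerance evolution, event intensity constant within
a scenario, and SST treated as a deterministic trend plus harmonic (no
interannual temperature noise outside events).  The γ and ε scales are
working values, not measurements; conclusions should be read at the level
of regime structure (recover / split / collapse) rather than exact terminal
percentages.
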