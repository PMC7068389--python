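# Methods

## Model and assumptions

The population under an age cutoff (default `max_age = 60`) is tracked by
single year of age. Each age `i` carries a recipient proportion `x(i)`;
the two-state split (in system / out of system) evolves by the annual,
column-stochastic transition

```
A(i) = [[1−q(i), p(i)], [q(i), 1−p(i)]]
```

applied simultaneously with ageing: the state at age `i`, time `t`
determines the state at age `i+1`, time `t+1`. The assumptions baked into
this structure are:

- **No mortality or migration** below the cutoff. Exit from the modelled
  window happens only by ageing past `max_age − 1`; that oldest cohort
  simply leaves the accounting.
- **Newborns inherit their mother's state**, and recipients and
  non-recipients share the same age-specific birth rates `b(i)`,
  supported on mothers aged 15–49 (the window is a `BirthSchedule`
  parameter so small test grids can declare their own). The raw
  birth-fed age-0 vector sums to `Σ b`, not 1, so it is renormalised to a
  proportion. Two normalisations are offered because the convention is
  genuinely open: `literal` (divide by `Σ b`; every fertile age counts by
  its rate alone) and `weighted` (weights `b(i)·w(i)`; accounts for the
  mothers' cohort sizes). `literal` is the default; results differ only
  when `x` varies across the fertile ages.
- **Time-constant schedules**: `p`, `q`, `b`, `w` are held fixed over the
  projection horizon. The weights `w` enter only through the overall
  proportion `X = Σ x(i) w(i)`.

Band-level inputs (e.g. decadal groups) are expanded piecewise-constant
to single ages — the same value at every age in the band. This
convention, applied to the packaged decadal exit schedule, reproduces the
published per-age first-exit and mean-time table at printed precision,
which is why it is adopted; no smoothing across band edges is attempted.
Probabilities are validated strictly in `[0, 1]` and never clipped
(`project_step` clips its output only against float roundoff at the
`1e−16` scale, where a convex combination of probabilities can land
marginally outside the unit interval).

## Sojourn analysis and censoring

For a recipient aged `i`, annual exit chances `q(i), q(i+1), ...` act as
independent Bernoulli trials until the cutoff. The first-exit probability
is `1 − Π (1−q(j))`; the waiting-time pmf is
`Pr(K=k) = q(i+k−1) Π_{m<k} (1−q(i+m−1))`, and the remaining mass is the
censoring probability (still in the system at the cutoff).

The headline `mean_time` is the **unconditional** mean `Σ k·Pr(K=k)` in
which censored individuals contribute zero years. This is a deliberate
choice: it is the quantity that reproduces the published reference table
(e.g. starting age 55 → 1.31 years despite 52% censoring). Because many
users expect the mean **among leavers**, that quantity is exposed
separately as `conditional_mean_time = mean_time / first_exit_prob` and
never conflated with the headline figure. Rendered tables round
probabilities to 5 decimals and means to 2, matching the reference
presentation; serialised CSV/JSON keeps full precision.

## Elasticity analysis

For each age group and each parameter (group entry probability, group
exit probability) the rate of change of the overall proportion is a
central finite difference

```
ΔX/Δθ ≈ (X(θ+h) − X(θ−h)) / 2h
```

where the same additive `h` is applied to every single age in the group
and `X` is evaluated after `horizon` projection steps (default 1). In
relative mode (default) `h = step × θ̄` with `θ̄` the group mean of the
per-age baseline values (on band-constant inputs this is the band value)
and `step = 1e−6`; absolute mode uses `h = step` directly. Perturbations
that push any probability outside `[0, 1]` raise an error rather than
silently truncating.

Over one step `X` is an affine function of each group parameter, so the
central difference is exact up to rounding and demonstrably step-size
independent; the default tiny step therefore costs nothing in accuracy.
The elasticity is `δ = (ΔX/Δθ) · θ̄ / X` with `X` the baseline projected
proportion — the % change in X per 1% change in the parameter. Group
rows are classified `Entering` / `Leaving` / `Tie` by comparing
`|δ_p|` and `|δ_q|`; tables report absolute values by convention, with
signs available via `signed=True` (entry rates are ≥ 0 and exit rates
≤ 0 whenever every `x(i)` is interior).

Child entry (ages 0–9) is perturbed independently of the adult groups.
Substantively, children enter through their parents' means test, so a
policy lever on child entry is really a lever on parental income; the
model keeps the groups mechanically independent and leaves that coupling
to interpretation.

The published group-level rates of change for this system (~0.6) cannot
be checked here: they depend on population weights and birth rates that
were never published, and a one-step projection under any near-uniform
weight vector gives rates an order of magnitude smaller. The elasticity
machinery is therefore validated by analytic properties (step-size
independence, the definitional identity `δ = rate·θ̄/X`, symbolic
differentiation on a 3-age toy) and by the published classification
labels, not by the published numeric table.

## Synthetic inputs

`generate_synthetic_inputs` emulates the structure of registry-derived
schedules for a low-fertility, means-tested setting:

- exit `q`: hump-shaped over age, peaking near the mid-20s at about
  0.2/yr and declining toward 0.12/yr — exits are driven by labour-market
  re-entry, easiest for young adults;
- entry `p`: a childhood plateau near 0.03/yr decaying to an adult floor
  of about 0.003/yr — children enter via their parents; `q > p` is
  enforced at every age;
- births `b`: bell over ages 15–49 scaled so `Σ b` equals a
  total-fertility proxy (default 1.2);
- weights `w`: a gentle taper with age; initial `x` near 4% overall,
  higher for children.

Mild smoothed log-normal noise (scale 0.1) makes each seed a distinct but
structurally identical scenario; generation is byte-deterministic given
the seed (one `numpy` generator per call, no global state). The generator
emulates *structure*, not Hong Kong census magnitudes: passing tests show
the machinery is correct under realistic regimes, not that any specific
real-world projection is right. Real registry data also have features the
generator omits entirely — time-varying rates, household clustering
(whole households enter and leave together), socioeconomic and gender
heterogeneity, mortality.

## Microsimulation oracles

Two agent-level simulators provide brute-force cross-checks:

- `simulate_cohort`: `n` recipients of one age draw independent annual
  exit Bernoullis; waiting times are recorded with 0 encoding censoring
  at the cutoff, so the empirical exit fraction and censored-as-zero mean
  converge to the closed-form values.
- `simulate_population`: each age slot holds a fixed sample of
  `m = n // max_age` agents representing that age's proportion; ageing
  shifts samples up one slot, transitions use the per-age `p`/`q`, and
  each newborn agent copies the current state of a random agent at a
  mother age drawn ∝ `b` (literal mode) or ∝ `b·w` (weighted mode). Slot
  expectations equal the deterministic recursion exactly, so the weighted
  overall proportion is an unbiased estimate of the projected `X` with
  per-period standard error `√(Σ w(i)² x(i)(1−x(i)) / m)`.

Agreement tests use 3-standard-error bands over 20 fixed seeds with
cohorts of 100,000 and populations of 120,000 agents over 6–8 periods —
sizes chosen to keep Monte-Carlo error a small fraction of the signal
while the whole suite runs in a few seconds.

## Numerical and design notes

- Mass conservation is structural (each column of `A(i)` sums to 1;
  `y = 1 − x` is implicit), checked to `1e−12` in tests.
- The mean-time recursion `D(i) = q(i) + (1−q(i))(D(i+1) + F(i+1))`
  (with `F` the first-exit probability) is used as an independent route
  to the sojourn mean, never forming the pmf.
- Band labels accept both ASCII hyphen and en-dash on input; outputs use
  the hyphen. CSV writers emit `repr(float)` so reader/writer round-trips
  are exact.
- Degenerate inputs fail loudly: an all-zero birth schedule (undefined
  newborn composition), a zero baseline `X` (undefined elasticity),
  gapped or overlapping bands, out-of-range probabilities.

## Limitations

- No mortality, migration, or ages 60+: the cutoff treats survival to 60
  in-system as censoring, nothing more.
- Entry/exit probabilities are first-order Markov in age and state; real
  spell data show duration dependence the model cannot express.
- Group perturbations are uniform within a band; distributional shifts
  inside a band are invisible.
- The elasticity horizon default of 1 year answers a short-run question;
  long-run stationary elasticities can differ in both size and ranking
  (the `horizon` parameter exists for this).
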