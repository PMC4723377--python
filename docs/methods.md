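# Methods

This note records the mathematical model, the estimation procedure, the
numerical choices behind them, and the known limitations. Everything
stated here about behaviour of the code is either a mathematical property
of the model or was computed with the package itself (the test suite and
`scripts/acceptance.py` reproduce the computations).

## Model

Topic diffusion in a web forum is modelled as an SIR epidemic over
authors, with the susceptible pool replenished by logistic growth of the
total population toward a carrying capacity:

    dS/dt = mu * ((K - N)/K) * N - alpha * S * I
    dI/dt = alpha * S * I - beta * I
    dR/dt = beta * I,        N = S + I + R

- `S(t)` — users who might start posting on the topic (susceptibles),
- `I(t)` — currently active authors (infectives); this is the observable,
  matched against per-month distinct-author counts,
- `R(t)` — past authors whose posts have lost influence (recovered),
- `alpha` — infection rate per susceptible–infective pair per month,
- `beta` — recovery rate per infective per month,
- `mu` — logistic recruitment rate (may exceed 1, unlike `alpha`, `beta`
  which live in `[0, 1)`),
- `K` — carrying capacity, the largest author pool the topic can recruit.

The time unit is one month throughout; all rates are per month and the
observation grid is integer months.

The **effective reproduction ratio** `alpha * S(0) / beta` is the average
number of new authors recruited by one active author at onset. By the
threshold principle, values above 1 predict initial growth of `I(t)`
(an outbreak), values below 1 predict die-out; at the threshold,
`dI/dt(0) = 0` exactly, and the test suite verifies the sign agreement of
`dI/dt(0)` and `alpha*S(0) - beta` across a parameter sweep.

## Time-series preparation

- A post belongs to the calendar month (UTC) of its timestamp; the
  distinct-author count of a topic-month is the number of unique author
  ids with at least one post in that month. Months without posts between
  the first and last observed post are zero-filled so the ODE fit sees a
  regular grid.
- Smoothing is a trailing, edge-truncated moving average (the first
  `w - 1` values average over all available history). Trailing alignment
  keeps the filter causal, so it could be applied in a live monitoring
  setting; it also preserves series length.
- The spike rule flags periods whose count strictly exceeds
  `mean + 2 * sd`, with `sd` in the population (divide-by-n) convention.
  Strictness makes the zero-variance case unambiguous: a constant series
  has threshold equal to every value and reports no spikes. A topic with
  at least one spike is *spikey*; otherwise *chatter*. Chatter topics are
  excluded from fitting by default (`--include-chatter` overrides).

Two properties of the spike rule worth knowing:

- It is invariant under a constant shift of the series (threshold and
  data move together).
- It reacts to the **shape** of the series, not to the reproduction
  ratio: a steeply decaying series can be flagged spikey by its first
  point alone, and a slow outbreak barely above threshold (ratio ~ 1.1)
  produces a broad hump that never exceeds `mean + 2 sd`. "Spikey"
  should therefore be read as "burst-shaped", not "super-threshold";
  only clearly super-threshold outbreaks are reliably classified spikey.

## Objective and goodness of fit

The estimand is `theta = (alpha, beta, mu, S0, K)`. Initial conditions
follow the convention `I(0) = first observed count` and `R(0) = 0`
(leading all-zero periods are trimmed first); `S0` is estimated.

The objective is the residual sum of squares on the observation grid,

    SSR(theta) = sum_i ( I_i - I_hat(t_i; theta) )^2,

minimized over a box-shaped feasible set. Reported metrics are
`MSE = SSR / n` and `R^2 = 1 - SSR / SST`; `R^2` may be negative and is
undefined (reported as NaN with a warning) for a constant observed
series. Candidates whose simulation blows up, or with `N(0) > K` or
`alpha >= 1`, receive a large finite penalty (`1e12`) so the optimizer
keeps running.

## Genetic algorithm

A real-coded generational GA with the classic operator set:

- **Linear-ranking fitness** (selective pressure `SP` in `[1, 2]`):
  individuals ranked by objective, `fitness(r) = 2 - SP +
  2 (SP - 1)(r - 1)/(N - 1)`; fitness always sums to `N`.
- **Roulette-wheel selection** proportional to fitness, with replacement.
- **Single-point crossover** at gene boundaries (cut uniform in
  `{1, …, L-1}`); gene values are exchanged, never altered.
- **Real-value mutation**: `gene ± r * 2^(-u k)` with `u ~ U[0, 1]`,
  range `r = 0.1 * (upper - lower)`, precision `k = 16`, clipped into the
  bounds. Half the probability mass of the step factor lies below
  `2^(-8)`, giving fine local search.
- **Elitism** (1 by default) makes the best objective non-increasing
  across generations.

Defaults: population 100, 500 generations, crossover probability 0.8,
per-gene mutation probability 0.1, `SP = 2`, elitism 1, seed 0. Identical
seed, configuration and data give bit-identical results.

### Gene parametrization

The GA does **not** search `(alpha, beta, mu, S0, K)` directly. Early
experiments showed that landscape to be deceptive: near onset the data
constrain only the product `alpha * S0` (the force of infection per
active author), so the least-squares surface has a narrow curved ridge
in the `(alpha, S0)` plane, and a broad recruitment-only basin
(`alpha ~ 0`, growth explained by `mu` alone) attracts almost all of the
uniform initialization mass. Axis-aligned mutation cannot descend a
curved ridge, and runs stalled far above the optimum.

The internal gene vector is therefore `(lambda0, beta, mu, S0, K)` with
`lambda0 = alpha * S0`; `alpha = lambda0 / S0` is recovered for
reporting, and every public interface (objective, parameter files, fit
tables) stays in `alpha`-space. This puts the identifiable quantity on a
single gene axis where crossover and mutation act on it directly.

### Default bounds

Data-scaled, for observed counts with peak `P`, first count `I0`:
`lambda0 in [0, 10]` (an author recruiting more than ~10 new authors per
month is beyond what monthly counts can resolve), `beta in [0, 1)`,
`mu in [0, 2]` (an author pool more than doubling per month is already
extreme), `S0 in [I0, 20 P]`, `K in [N0, 50 P]`. A bound pair with equal
endpoints freezes that gene, which is how reduced sub-problems (e.g. the
two-free-parameter grid-search comparison in the tests) are expressed.

### Local polish and restarts

Two pragmatic additions, both exposed as parameters:

- `local_polish` (**on** by default): a derivative-free Nelder–Mead
  refinement of the GA's best candidate, clipped to the bounds. The GA
  locates the right basin but descends its curved valley slowly; the
  simplex finishes the descent (on noiseless synthetic outbreaks it
  turns near-recoveries with residual objective up to ~50 into exact
  recoveries with objective ~1e-9). Set `local_polish=False` for the
  bare GA.
- Stall-triggered restart (`restart_after=50`, `restart_tol=1e-3`): if
  the best objective fails to improve by 0.1% relative for 50
  generations, the population is reseeded uniformly with the incumbent
  kept in slot 0. This is a standard remedy for premature convergence on
  deceptive landscapes.

## Numerical integration

Three integration paths, with distinct roles:

- **Public simulation** (`simulate`): scipy's adaptive RK45 with
  `rtol = 1e-6`, `atol = 1e-9`, reporting at integer months. The exact
  system preserves non-negativity, so compartment excursions below
  `-1e-6` abort with an error; smaller ones are clipped to zero. A
  discrete Euler mode (`euler=True`, step = 1 month) exists for
  comparison with difference-equation treatments.
- **GA objective** (`integrate_population`): classical RK4 with fixed
  step `h = 0.1` month, vectorized across the whole candidate
  population (the state is a `(3, m)` array). The GA evaluates
  `population x generations` candidates; integrating each through the
  adaptive solver would dominate the run time. At `h = 0.1` the worst
  relative difference from the adaptive solver over randomly drawn
  feasible parameter sets is about `8e-4` — orders of magnitude below
  observation noise and fit tolerances. Wild candidates that blow up
  yield NaN and take the failure penalty instead of aborting the sweep.
- A scalar twin of the vectorized RK4 (same operation order,
  bit-identical output) serves single-candidate objective calls during
  the simplex polish, where array overhead would dominate.

The test suite pins the adaptive path against a fixed-step RK4 oracle at
`h = 0.001` and against closed forms in the two degenerate limits
(`alpha = mu = 0`: exponential decay; `alpha = beta = 0`: logistic
growth).

## Synthetic data generator

The generator exists so every stage is testable with known ground truth:

- `generate_series` observes `I(t)` at integer months, optionally with
  Gaussian noise (sd = `noise_scale` × peak `I`, clipped at zero) or
  Poisson noise (mean `I(t)`).
- `generate_post_log` fabricates a forum-style log whose per-month
  distinct-author counts equal `round(I(m))` by construction; a
  configurable fraction of authors carries over between months so logs
  look forum-like, without affecting distinctness.

Generator limits to keep in mind:

- The model is deterministic; only *observation* noise is modelled.
  There is no process noise, no network structure, no competing topics.
- Clipping Gaussian noise at zero biases small counts upward (the noise
  cannot push a near-zero count down as far as up). This matters for
  fitting onset months — see Limitations.
- Months where `I(t)` rounds to zero produce no posts, so a counted
  series spans first-to-last active month only.

## Limitations

- **`alpha` and `S0` are only jointly identified.** Near onset the
  likelihood constrains `lambda0 = alpha * S0`; separating the factors
  relies on the late, saturating part of the trajectory. Reported
  `alpha` and `S0` should be interpreted through their product unless
  the series clearly saturates.
- **`beta` is not recoverable from noisy onset-limited data.** On
  synthetic outbreaks that start at `I(0) = 1` with Gaussian
  observation noise of sd = 10% of peak, the global least-squares
  optimum itself — not an optimizer artifact — places `beta` at or near
  the upper bound while preserving `lambda0`: profiling the objective
  over fixed `beta` (all other genes re-optimized) is monotone
  decreasing toward `beta -> 1`, and a simplex started at the true
  parameters descends to a lower objective than the truth's. The
  mechanism is the onset: noise of that magnitude obliterates the early
  months that carry the recovery-rate information, the
  first-observation `I(0)` convention anchors the fit to a noisy value,
  and zero-clipping biases early counts upward, favouring faster
  dynamics. One acceptance test encoding a 25%-relative `beta` recovery
  target under exactly these conditions is left failing rather than
  weakened; noiseless recovery under the same protocol is exact in
  10/10 seeds.
- **Spike classification is shape-based.** See the time-series section:
  near-threshold outbreaks read as chatter; steep decays can read as
  spikey.
- The fitter assumes a single topic with a single outbreak on a regular
  monthly grid; multi-wave series violate the model class.
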