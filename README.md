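# sirdiffusion

SIR-with-logistic-recruitment modelling of topic diffusion in web
forums: turn post logs into monthly distinct-author series, detect
activity bursts, and fit an epidemic model to them with a genetic
algorithm.

## The science in one paragraph

Discussion topics spread through a forum like infections through a
population: users who might start posting are *susceptible* (`S`),
currently active authors are *infective* (`I`), and past authors whose
posts have lost influence are *recovered* (`R`). Unlike the classical
closed-population SIR model, the author pool is replenished — new users
keep discovering the forum — which is modelled as logistic growth of the
total population `N = S + I + R` toward a carrying capacity `K`:

```
dS/dt = mu * ((K - N)/K) * N - alpha * S * I
dI/dt = alpha * S * I - beta * I
dR/dt = beta * I
```

All rates are per month. The observable is `I(t)`: the number of
distinct authors posting on the topic each month. Fitting
`theta = (alpha, beta, mu, S0, K)` to an observed series by nonlinear
least squares yields interpretable quantities — most usefully the
effective reproduction ratio `alpha * S(0) / beta`, the number of new
authors one active author recruits at onset. Above 1 the topic breaks
out; below 1 it dies off. Because the least-squares surface is
multimodal with narrow curved valleys, the optimizer is a real-coded
genetic algorithm (linear-ranking selection, single-point crossover,
real-value mutation) followed by a simplex polish; see
[docs/methods.md](docs/methods.md) for the full estimation story,
including what is and is not identifiable.

## Worked example

Generate a noisy synthetic outbreak with known ground truth, screen it
for bursts, and recover the parameters:

```python
import numpy as np
import sirdiffusion as sd

params = sd.SIRParams(alpha=0.02, beta=0.7, mu=0.05, K=500.0)
init = sd.InitialState(S0=100.0, I0=1.0)
print("reproduction ratio:", round(sd.effective_reproduction_ratio(params, init.S0), 2))

spec = sd.SyntheticSpec(params=params, init=init, horizon=24,
                        noise_model="gaussian", noise_scale=0.05, seed=42)
series, trajectory = sd.generate_series(spec)
print("counts:", np.round(series.counts[:8], 1))

report = sd.detect_spikes(series)
print("classified:", sd.classify_topic(series),
      "| spike months:", report.spike_periods,
      "| threshold:", round(report.threshold, 1))

est = sd.GASIRFitter(random_state=0).fit(series.counts)
print(f"alpha={est.alpha_:.4f} beta={est.beta_:.3f} mu={est.mu_:.3f} "
      f"S0={est.s0_:.1f} K={est.k_:.0f}")
print(f"MSE={est.mse_:.2f} R2={est.r_square_:.4f}")
print("alpha*S0:", round(est.alpha_ * est.s0_, 3), "(true 2.0)")
```

Output (the run takes ~10 s, dominated by the 500-generation GA):

```
reproduction ratio: 2.86
counts: [ 1.6  1.7 14.  31.4 34.3 29.3 22.5 14.3]
classified: spikey | spike months: [3, 4, 5] | threshold: 29.0
alpha=0.0194 beta=0.680 mu=0.051 S0=96.3 K=479
MSE=1.90 R2=0.9778
alpha*S0: 1.868 (true 2.0)
```

At 5% observation noise the fit recovers the recovery rate `beta`
(0.680 vs 0.7), the force of infection `alpha*S0` (1.87 vs 2.0) and the
carrying capacity (479 vs 500). `GASIRFitter` is a scikit-learn-style
estimator: `fit` / `predict` / `get_params` / `set_params` all work, and
fitted attributes carry the trailing underscore. Functional wrappers
(`sd.fit`, `sd.objective`, `sd.detect_spikes`, …) cover every estimator
for script use.

## Command line

The same stages are available as CLI verbs:

```
sirdiffusion synth posts --spec spec.yaml --out posts.csv   # ground-truth post log
sirdiffusion prepare --posts posts.csv --topic demo --out series.csv
sirdiffusion spikes --series series.csv
sirdiffusion fit --series series.csv --seed 17 --out fit.json
sirdiffusion simulate --params params.json --horizon 30 --out traj.csv
sirdiffusion run --posts posts.csv --out-dir results/ --seed 1
```

`run` executes the full pipeline — per-topic series, spike screen
(chatter topics are excluded from fitting unless `--include-chatter`),
GA fits — and writes a fit table (MSE, R², S(0), α, β, μ, K per topic),
per-topic trajectory CSVs of the estimated S/I/R overlaid on the
observations, and a `manifest.json` that suffices to re-run the
identical pipeline.

## Repository layout

```
src/sirdiffusion/
  model.py        dynamical system, adaptive simulation, reproduction ratio
  timeseries.py   post-log aggregation, moving average, spike detection
  ga.py           genetic-algorithm operators (ranking, roulette, crossover, mutation)
  fitting.py      least-squares objective, metrics, GASIRFitter
  synthetic.py    ground-truth series and forum-style post-log generators
  pipeline.py     prepare -> screen -> fit report bundles
  cli.py          click command-line interface
  io.py           CSV/JSON/YAML formats
docs/methods.md   model, estimation design, numerics, limitations
tests/            unit, property and acceptance tests
scripts/          acceptance.py
```
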