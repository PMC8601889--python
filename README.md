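# phytoedm

Does aggregating phytoplankton species into assemblages make their monthly
dynamics easier to forecast?  `phytoedm` is a pipeline for answering that
question with univariate empirical dynamic modeling (EDM): it forecasts
monthly abundance series one month ahead by simplex projection, compares the
skill against a seasonality-only surrogate null, and runs Monte-Carlo
experiments in which random assemblages of increasing size are summed and
forecast.  It is aimed at plankton ecologists and time-series modellers
working with long monthly monitoring records (station-style data: a couple of
hundred taxa, a couple of decades, occasional missed cruises).

## Method

A single series x_t (cells L⁻¹) on a monthly grid is delay-embedded as
vectors (x_t, x_{t−1}, …, x_{t−(E−1)}).  For each vector, the E+1 nearest
neighbours among the other vectors (leave-one-out) predict the next month as
a weighted mean of the neighbours' continuations,

    x̂_{t+1} = Σ_s w_s x_{s+1} / Σ_s w_s ,   w_s = exp(−d(p_t, p_s)/d_min) ,

and skill is ρ = Pearson(x_{t+1}, x̂_{t+1}) over all forecast pairs.  The
embedding dimension E is scanned over 1–10 and the best-skill E kept.  Months
lost to missed sampling propagate: vectors or targets touching a gap are
dropped, never interpolated.

An assemblage of k taxa is the per-month arithmetic sum of k member series;
at each assemblage size the pipeline draws many random assemblages (optionally
restricted to a functional group or a cell-size class), forecasts each
aggregate, and reports the mean skill ρ̄ with a ±1.96 × SE band.  The
seasonal null rebuilds each series as climatology + shuffled anomalies and
forecasts that instead; skill above the null reflects dynamics beyond
seasonality.

Two generative models probe what shapes the skill-versus-size curve: a
seasonal sine with species-specific phase and additive observational noise,
and a 100-species stochastic Lotka-Volterra community with seasonal carrying
capacity, sparse monthly-redrawn interactions, and monthly process noise on
growth rates, integrated with a 6-hour Euler step and averaged to months.
A synthetic data generator emulates the statistical shape of a real coastal
station record (198 taxa in 5 functional groups and 3 size classes, 267
months, 10 shared gaps, lognormal abundance spread) so the whole pipeline is
testable without the original data.  See `docs/methods.md` for assumptions
and numerical choices.

## Worked example

Forecast skill versus assemblage size for the high-noise observational model
(noise scale γ = 1, 100 species, 240 months):

```python
from phytoedm import (NoiseModelParams, simulate_noise_model,
                      predictability_curve)

table = simulate_noise_model(NoiseModelParams(gamma_obs=1.0), rng_seed=0)
curve = predictability_curve(table, sizes=[1, 10, 100], n_trials=50,
                             n_surrogates=20, rng_seed=0)
for s in curve:
    print(f"size {s.assemblage_size:>3}  rho = {s.mean_rho:.3f} "
          f"+- {s.ci95_half_width:.3f}   surrogate rho = {s.mean_surrogate_rho:.3f}")
```

prints

```
size   1  rho = 0.399 +- 0.019   surrogate rho = 0.414
size  10  rho = 0.852 +- 0.005   surrogate rho = 0.857
size 100  rho = 0.985 +- 0.000   surrogate rho = 0.985
```

Single noisy species are poorly predictable (ρ̄ ≈ 0.4); summing 100 of them
dilutes independent noise and skill approaches 1 — the portfolio effect.  The
surrogate null tracks the real skill here because this model contains no
dynamics beyond its seasonal cycle; on real or interacting-community data the
null falls below the real skill.  The band at size 100 is zero because only
one 100-of-100 assemblage exists.

The same experiments are available from the shell:

```sh
phytoedm curve --preset noise-sweep --n-trials 50 --seed 0 --out results/
phytoedm synth-l4 --seed 0 --out synthetic/
phytoedm predict --abundance synthetic/synthetic_l4_abundance.csv \
    --metadata synthetic/synthetic_l4_metadata.csv --taxon tax000
```

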