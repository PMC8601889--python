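# Methods

This note documents the models, conventions, and numerical choices behind
`phytoedm`, in the order the pipeline uses them.

## Time-series container

All analyses run on monthly abundance series (cells L⁻¹) on a strictly
consecutive calendar grid; a missed sampling month is an explicit `NaN`, so
no operation ever has to guess about alignment.  Measured abundances must be
non-negative; derived series (seasonal surrogates, whose relocated anomalies
can undershoot the climatology) may carry negative values and are flagged as
such.

## Simplex projection

Forecasting is classic univariate simplex projection: delay-embed with lag
τ = 1 month, predict tp = 1 month ahead from the E+1 nearest neighbours
under exponential distance weighting `w = exp(−d/d_min)`.  Conventions the
classic description leaves open are fixed as follows:

* **Cross-validation.** Leave-one-out excludes only the target's own delay
  vector from the neighbour library; no temporal exclusion radius.  Library
  membership additionally requires the library point's own one-month
  continuation to be observed.
* **Skill.** ρ is the raw Pearson correlation of (observed, predicted)
  pairs and is reported unclamped; negative values (worse-than-mean
  forecasts) participate in Monte-Carlo averages, because clamping at zero
  would bias ρ̄ upward for noisy assemblages.  Meaningful skill lives in
  [0, 1].
* **No normalisation.** Series are embedded raw.  Pearson correlation is
  invariant to affine rescaling of the series, and the aggregation
  experiments are defined on raw cell-density sums.
* **Degenerate distances.** If the nearest neighbour distance is zero, every
  exact duplicate of the target pattern joins the neighbour set with weight
  1 (the set may then exceed E+1); remaining selected neighbours are
  weighted `exp(−d/d̃)` with d̃ the smallest nonzero selected distance; if
  all selected distances are zero the weights are uniform.  Distance ties
  resolve to the earlier library time (stable sort).
* **Feasibility.** A forecast needs at least 3 valid pairs; with fewer than
  E+1 library points, all available are used.  Pearson is undefined when
  either side of the pairs is constant; such forecasts raise and, inside
  Monte-Carlo loops, the trial is excluded and counted.
* **Embedding selection.** E is scanned over 1–10 (configurable) and the
  highest-ρ result kept; ties within 10⁻⁹ resolve to the smallest E, so a
  noiseless periodic series reports the most parsimonious embedding.
* **Missing data.** Gaps propagate (vectors and targets touching a gap are
  dropped).  No interpolation: monthly averaging upstream already minimises
  gaps, and the residual ones are rare enough that dropping is cheaper than
  defending an imputation model.

The implementation is vectorised (full pairwise distance matrix per series,
~250 points); a deliberately naive loop-and-sort implementation in the test
suite serves as an independent oracle at 10⁻¹² agreement.

## Seasonal surrogate null

The null preserves seasonality and destroys anomaly dynamics: per calendar
month climatological means (requiring every calendar month observed at least
once), residuals shuffled uniformly **across all observed positions** — not
within calendar months, which would preserve exactly the seasonal variance
structure under test — and added back to the tiled climatology.  The shuffle
is a permutation (no replacement), so the residual multiset and its sum are
conserved exactly.  Missing months stay missing, keeping real and surrogate
skill on identical support.  Surrogate i of a batch derives its generator
from (master seed, i), so any single surrogate is regenerable.

## Assemblage experiments

An assemblage is the per-month sum of its members, missing whenever any
member is missing; summation order is fixed by sorted taxon id for bit-level
reproducibility.  Sampling strategies: uniform over the whole community, a
single functional group (diatom, dinoflagellate, coccolithophore,
phytoflagellate — a singleton catch-all group is not a valid stratum), or a
cell-radius class (<5 µm, 5–12 µm inclusive, >12 µm).  Trials draw members
without replacement within a trial and independently across trials, so every
pool member has equal inclusion probability and repeated combinations are
possible (inevitable near the pool size).  Per size the summary is the mean
trial skill, SE (sample SD / √n), and a ±1.96 × SE band; at size = pool
size every trial is identical and the band is exactly zero.  Trial j at
size s derives its seed from (master, s, j).

The exclusion filter ranks taxa by mean observed abundance or by univariate
skill and removes the top ⌈fraction·N⌉ (ties by taxon id; taxa whose
forecast fails rank last).  The coefficient of variation of an aggregate
(sample SD / mean over observed months) is the portfolio-effect diagnostic:
for independent same-scale members it falls like 1/√M.

Full study scale is 1000 trials per size and 100 surrogates per trial; the
bundled presets and tests run 10–100 trials per size, which is enough to
separate the curves they assert about at their ±1.96 × SE bands.

## Observational-noise model

Each species is `x_t = A sin(ωt + φ) + A + γ_obs ε_t + β` with A = 1,
ω = 2π/12 rad month⁻¹, φ uniform in [−1, 1] rad, ε ~ N(0, 1) i.i.d. per
species-month, γ_obs in {0, 0.5, 1}, 100 species × 240 months.  The offset
β = −min_t(γ_obs ε_t), per species, pins the minimum noise contribution at
zero and guarantees x ≥ 0; being constant per series it cannot affect
correlation-based skill.  Noise is drawn independently per species-month, so
aggregation dilutes it while the phase-aligned seasonal parts reinforce.

## Lotka-Volterra community model

`dx_i/dt = r_i(t) x_i (1 − Σ_j α_ij x_j / K(t))` with 100 species over 20
years, integrated by forward Euler at the model's native 6-hour step
(dt = 0.25 day) on a 360-day calendar (ω = 2π/360 rad day⁻¹, 30-day months,
120 steps per month), then averaged within months to a 240-month table.

* **Carrying capacity.** `K(t) = K·(A sin ωt + δ)` with K = 30 000 cells
  L⁻¹, δ = A + 0.1.  The multiplicative grouping is forced: adding δ
  outside the product could not keep K(t) positive.
* **Interactions.** Each species has a fixed random partner set of a quarter
  of the community; partner strengths are redrawn uniformly in ±α every
  month (α = 0 or 0.25).  The diagonal is 1 always: without self-limitation
  the α = 0 treatment would be unbounded exponential growth rather than
  seasonal logistic dynamics.
* **Growth rates.** `r_i(t) = max(0, μ_i A sin ωt + μ_i + γ_p ε_i,m)` with
  μ_i uniform in [0.8, 1.2] day⁻¹ and ε redrawn per species per month and
  held within the month (environmental anomalies persisting for weeks).
  The clamp at zero is the non-negativity offset, and per-step clamping is
  the only formulation that works: r < 0 while x sits above a declining
  K(t) flips the logistic's stability and the trajectory diverges (true of
  the ODE, not just of Euler), while a constant per-species offset large
  enough to avoid that (minus the most negative draw of the run) makes
  every rate so large that abundances equilibrate to K(t) within days —
  the fixed point does not depend on r, so the noise would leave no imprint
  at all and the stochastic treatment would collapse onto the deterministic
  one.  Clamping keeps r ≥ 0 everywhere, makes the realized minimum rate
  exactly zero on any noisy run, and lets strongly negative noise months
  stall growth, which is how process noise becomes visible in the monthly
  series.
* **Floor.** After every step abundances below 10⁻¹⁰ cells L⁻¹ are reset to
  that floor, preventing extinction under negative interaction pressure.
* **Initial conditions and burn-in.** x_i(0) uniform in [0.1 K, 0.5 K] per
  run seed.  With day-scale growth rates the transient decays within weeks;
  no burn-in is excluded from skill computation (periodicity diagnostics in
  the tests drop the first two years).
* **Scheme adequacy.** Euler at the native step is the minimal scheme
  consistent with a fixed 6-hour step; the noise-free run agrees with a
  10× finer integration to <1% relative error on monthly means (tested).

## Synthetic station community

The generator emulates the statistical shape of a long-term coastal station
record: 198 taxa (130 diatoms, 37 dinoflagellates, 16 coccolithophores, 14
phytoflagellates, 1 other), radii filling size classes of 68/63/67 (44/40/46
within diatoms), a 267-month grid (Oct 1992–Dec 2014) with the same 10
randomly placed missing months in every series (one station calendar — a
missed cruise affects all counts).  Each taxon is an annual bloom
`scale · exp(κ(cos(2π(t − peak)/12) − 1))` under mean-preserving lognormal
noise: scale log-uniform over 10¹–10⁵ cells L⁻¹ (abundant to rare), bloom
sharpness κ ~ U(0.5, 3), noise σ ~ U(0.3, 1).  Bloom months are drawn from
a concentrated productive season (wrapped Normal, mean May, SD 2 months):
temperate coastal communities bloom coherently, and this shared seasonal
component is what aggregation amplifies while taxon-level noise cancels —
with incoherent bloom timing assemblages would gain no skill, which is not
how such stations behave.  Multiplicative noise (not additive Gaussian)
keeps rare taxa non-negative and right-skewed.

The predictability-gradient variant relabels a chosen fraction of taxa as
low-noise (κ = 2, σ = 0.1, high skill) and the rest as noisy (κ ~ U(0.5,
1.5), σ = 1.2 — seasonal but swamped, individually near-unpredictable),
preserving each taxon's mean abundance and the gap calendar, and returns
ground-truth labels for validating ranking-based filters.

What passing tests on this generator do **not** show: real records have
trends, regime shifts, zero-inflation from detection limits, correlated
noise across taxa (shared weather), and taxonomically structured bloom
timing; none of these are emulated, so pipeline behaviour on real data can
differ in degree, though the portfolio-effect mechanics are generic.

## Reproducibility

All randomness flows through seeded generators; composite seeds are derived
with `SeedSequence((master, …))` so any trial, surrogate, or simulation is
regenerable in isolation.  Identical configuration and seed give
byte-identical result files, and every results CSV is accompanied by a
provenance JSON sufficient to regenerate it.

## Known limitations

Forecast horizon is fixed at one month and embeddings are univariate by
design (no S-map, convergent cross-mapping, or multiview embedding).  The
surrogate null assumes a stable climatology (no trend removal).  The
community model's Euler step at strongly negative interaction pressure can
overshoot; the abundance floor bounds but does not smooth such excursions.
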