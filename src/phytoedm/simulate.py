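"""Generative community models: seasonal sine + observational noise, and a
stochastic Lotka-Volterra competition community.

Two idealized plankton communities used to probe what limits assemblage
predictability:

* **Observational-noise model** — every species is the same seasonal sine
  (amplitude A, period 12 months) with a species-specific phase, plus i.i.d.
  Gaussian measurement noise scaled by ``gamma_obs``.  An additive offset
  keeps abundances non-negative.

* **Community model** — N species under Lotka-Volterra competition
  ``dx_i/dt = r_i(t) x_i (1 - sum_j a_ij x_j / K(t))`` with a seasonally
  varying carrying capacity, growth rates modulated by monthly process noise
  (``gamma_p``), and sparse random interactions: each species interacts with
  a fixed quarter of the community, with strengths redrawn uniformly in
  ``+-alpha`` every month.  Integration is forward Euler at a 6-hour step on
  a 360-day year; 6-hourly states are averaged to monthly values.

Non-negativity offsets: in the observational-noise model each species'
noise contribution is shifted by the negative of its own minimum over the
realized path, pinning the smallest contribution at exactly zero and
guaranteeing ``x >= 0`` (the shift is constant per species, so it changes
no correlation-based skill).  In the community model the growth rate is
clamped at zero per step — see :func:`realized_growth_rate` for why a
constant offset cannot work there.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrationDivergedError
from .timeseries import CommunityTable, MonthlyTimeSeries, TaxonRecord

__all__ = [
    "NoiseModelParams",
    "CommunityModelParams",
    "simulate_noise_model",
    "choose_partner_sets",
    "draw_interaction_matrix",
    "realized_growth_rate",
    "seasonal_carrying_capacity",
    "simulate_community_model",
]

DAYS_PER_YEAR = 360
DAYS_PER_MONTH = 30


@dataclass(frozen=True)
class NoiseModelParams:
    """Seasonal sine + observational noise.

    x_i(t) = A sin(omega t + phi_i) + A + gamma_obs * eps_i(t) + beta_i,
    eps ~ N(0, 1) i.i.d. per species-month, phi_i ~ U(phase_range),
    beta_i = -min_t(gamma_obs * eps_i(t)).
    """

    A: float = 1.0
    omega: float = 2 * math.pi / 12  # rad month^-1
    phase_range: tuple[float, float] = (-1.0, 1.0)  # rad
    gamma_obs: float = 0.0  # 0 none, 0.5 low, 1 high
    n_species: int = 100
    n_months: int = 240
    start: tuple[int, int] = (2000, 1)

    def __post_init__(self) -> None:
        if self.A <= 0 or self.gamma_obs < 0:
            raise ValueError("require A > 0 and gamma_obs >= 0")
        if self.n_months < 24:
            raise ValueError("need at least 24 months")


def simulate_noise_model(
    params: NoiseModelParams, rng_seed: int = 0
) -> CommunityTable:
    """Simulate the observational-noise community; deterministic per seed."""
    p = params
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed,)))
    phases = rng.uniform(*p.phase_range, size=p.n_species)
    eps = rng.standard_normal((p.n_species, p.n_months))
    t = np.arange(p.n_months)
    noise = p.gamma_obs * eps
    beta = -noise.min(axis=1)
    x = p.A * np.sin(p.omega * t[None, :] + phases[:, None]) + p.A
    x = x + noise + beta[:, None]
    x = np.maximum(x, 0.0)  # guard float round-off at the sine trough
    taxa = [
        TaxonRecord(
            taxon_id=f"sp{i:03d}",
            functional_group="other",
            cell_radius=1.0,
            series=MonthlyTimeSeries(p.start, x[i]),
        )
        for i in range(p.n_species)
    ]
    return CommunityTable(taxa)


@dataclass(frozen=True)
class CommunityModelParams:
    """Stochastic Lotka-Volterra community parameters.

    ``alpha`` bounds the uniform inter-species interaction strengths (0 for
    no interactions, 0.25 for strong); ``gamma_p`` scales monthly process
    noise on growth rates (0 or 1).  ``K`` is the carrying-capacity scale
    (cells L^-1); the seasonal capacity is K * (A sin(omega t) + delta) with
    delta = A + 0.1 keeping it strictly positive.  Basal growth rates mu_i
    are uniform in [0.8, 1.2] day^-1.  A floor of 1e-10 cells L^-1 prevents
    extinction under negative interactions.
    """

    alpha: float = 0.0
    mu_range: tuple[float, float] = (0.8, 1.2)  # day^-1
    K: float = 30_000.0  # cells L^-1
    A: float = 1.0
    omega: float = 2 * math.pi / DAYS_PER_YEAR  # rad day^-1
    delta: float = field(default=1.1)  # A + 0.1
    gamma_p: float = 0.0
    dt: float = 0.25  # day (6 h)
    years: int = 20
    n_species: int = 100
    interaction_fraction: float = 0.25
    abundance_floor: float = 1e-10  # cells L^-1
    x0_range: tuple[float, float] = (0.1, 0.5)  # fractions of K
    start: tuple[int, int] = (2000, 1)

    def __post_init__(self) -> None:
        if not self.delta > self.A:
            raise ValueError("delta must exceed A so K(t) stays positive")
        if not self.abundance_floor > 0:
            raise ValueError("abundance_floor must be positive")

    @property
    def n_months(self) -> int:
        return self.years * 12

    @property
    def steps_per_month(self) -> int:
        return round(DAYS_PER_MONTH / self.dt)


def choose_partner_sets(
    n_species: int, interaction_fraction: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Fixed interaction topology: each species draws floor(fraction * N)
    distinct partners (excluding itself)."""
    k = int(n_species * interaction_fraction)
    sets = []
    for i in range(n_species):
        others = np.delete(np.arange(n_species), i)
        sets.append(np.sort(rng.choice(others, size=k, replace=False)))
    return sets


def draw_interaction_matrix(
    n_species: int,
    alpha: float,
    partner_sets: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """One month's interaction matrix: diagonal 1 (self-limitation), partner
    entries uniform in (-alpha, alpha), all other entries 0."""
    A = np.eye(n_species)
    if alpha > 0:
        for i, partners in enumerate(partner_sets):
            A[i, partners] = rng.uniform(-alpha, alpha, size=partners.size)
    return A


def seasonal_carrying_capacity(t_day: float, params: CommunityModelParams) -> float:
    """K(t) = K * (A sin(omega t) + delta), strictly positive (delta > A)."""
    return params.K * (params.A * math.sin(params.omega * t_day) + params.delta)


def realized_growth_rate(
    mu_i: float,
    t_day: float,
    params: CommunityModelParams,
    eps_p_month: float = 0.0,
) -> float:
    """r_i(t) = max(0, mu_i A sin(omega t) + mu_i + gamma_p eps) (day^-1).

    The per-step offset (the clamp at zero) is what keeps the rate
    non-negative under process noise.  A negative growth rate cannot be
    allowed at all: with x above the seasonal capacity — routine while K(t)
    declines — ``r < 0`` flips the logistic's stability and the state
    diverges.  A single per-species offset large enough to prevent that
    (minus the most negative draw of the run) would instead make every rate
    so large that abundances track K(t) exactly and the noise leaves no
    imprint on the dynamics.  Clamping per step preserves both properties:
    ``r >= 0`` everywhere, the realized minimum of ``r`` over a noisy run is
    exactly 0, and months with strongly negative noise stall growth, which
    is how process noise shows up in the monthly series.
    """
    raw = (
        mu_i * params.A * math.sin(params.omega * t_day)
        + mu_i
        + params.gamma_p * eps_p_month
    )
    return max(0.0, raw)


def simulate_community_model(
    params: CommunityModelParams, rng_seed: int = 0
) -> CommunityTable:
    """Integrate the community model and aggregate to monthly means.

    Forward Euler at ``params.dt`` (6 h) over ``years`` 360-day years.
    Interaction strengths and per-species process noise are redrawn at every
    30-day month boundary and held within the month; after every step any
    abundance below the floor is reset to the floor.  Each monthly output
    value is the mean of the 120 post-step states within that month.

    Raises
    ------
    IntegrationDivergedError
        If the state becomes non-finite (with the offending step reported).
    """
    p = params
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed,)))
    n = p.n_species
    mu = rng.uniform(*p.mu_range, size=n)
    x0 = rng.uniform(p.x0_range[0] * p.K, p.x0_range[1] * p.K, size=n)
    partner_sets = choose_partner_sets(n, p.interaction_fraction, rng)
    eps = rng.standard_normal((n, p.n_months))

    steps = p.steps_per_month
    x = x0.copy()
    monthly = np.empty((n, p.n_months))
    interacting = p.alpha > 0
    for m in range(p.n_months):
        a_mat = draw_interaction_matrix(n, p.alpha, partner_sets, rng)
        noise_m = p.gamma_p * eps[:, m]
        acc = np.zeros(n)
        for s in range(steps):
            t_day = (m * steps + s) * p.dt
            sin_t = math.sin(p.omega * t_day)
            r = np.maximum(mu * (p.A * sin_t + 1.0) + noise_m, 0.0)
            k_t = p.K * (p.A * sin_t + p.delta)
            crowd = a_mat @ x if interacting else x
            x = x + p.dt * r * x * (1.0 - crowd / k_t)
            np.maximum(x, p.abundance_floor, out=x)
            acc += x
        if not np.all(np.isfinite(x)):
            raise IntegrationDivergedError(
                f"integration diverged in month {m} (day {t_day:.2f})"
            )
        monthly[:, m] = acc / steps

    taxa = [
        TaxonRecord(
            taxon_id=f"sp{i:03d}",
            functional_group="other",
            cell_radius=1.0,
            series=MonthlyTimeSeries(p.start, monthly[i]),
        )
        for i in range(n)
    ]
    return CommunityTable(taxa)
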