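"""Assemblage formation and Monte-Carlo predictability experiments.

An assemblage is the per-month arithmetic sum of member taxa's cell densities
(missing if any member is missing that month).  The experiments here draw
many random assemblages at each size — uniformly from the whole community or
restricted to a functional group or cell-size class — forecast each aggregate
with simplex projection, and summarise skill per size as a mean with a
+-1.96 x SE confidence band.  The rising, saturating skill-vs-size curve is
the portfolio effect: averaging imperfectly correlated members dilutes noise
and amplifies the shared seasonal signal.

Reproducibility: trial ``j`` at size ``s`` draws its members from
``SeedSequence((master_seed, s, j))`` and its surrogate ensemble from
``SeedSequence((master_seed, s, j, 1))``, so any single trial is regenerable
without rerunning the sweep.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .edm import EmbeddingConfig, select_embedding
from .errors import (
    EmptyAssemblageError,
    FilterTooAggressiveError,
    InvalidStrategyError,
    MemberNotFoundError,
    PoolExhaustedError,
    SeriesUnusableError,
    UndefinedCorrelationError,
    UndefinedCVError,
)
from .surrogates import surrogate_skill
from .timeseries import (
    FUNCTIONAL_GROUPS,
    SIZE_CLASSES,
    CommunityTable,
    MonthlyTimeSeries,
)

__all__ = [
    "Assemblage",
    "TrialSummary",
    "aggregate",
    "sample_assemblages",
    "predictability_curve",
    "coefficient_of_variation",
    "exclusion_filter",
]


@dataclass
class Assemblage:
    """A set of member taxa and their summed abundance series."""

    member_ids: frozenset[str]
    series: MonthlyTimeSeries


@dataclass
class TrialSummary:
    """Monte-Carlo summary for one assemblage size.

    ``n_trials`` counts successful trials entering the mean; ``se`` is the
    sample standard deviation of trial skills over sqrt(n_trials), and the
    95% band is ``+-1.96 x se``.  ``valid`` is False when every trial failed.
    """

    assemblage_size: int
    strategy: str
    n_trials: int
    mean_rho: float
    se: float
    ci95_half_width: float
    mean_surrogate_rho: float | None = None
    n_failed: int = 0
    valid: bool = True


def aggregate(table: CommunityTable, member_ids: Sequence[str]) -> Assemblage:
    """Sum member series month by month.

    A month is missing in the aggregate if any member is missing there.
    Summation order is fixed by sorted taxon id, so results are bit-level
    reproducible regardless of input ordering.
    """
    ids = sorted(set(member_ids))
    if not ids:
        raise EmptyAssemblageError("empty assemblage")
    missing = [i for i in ids if i not in table]
    if missing:
        raise MemberNotFoundError(f"member not found: {missing}")
    stack = np.stack([table[i].series.values for i in ids])
    total = stack.sum(axis=0)  # NaN in any member propagates
    return Assemblage(
        member_ids=frozenset(ids),
        series=MonthlyTimeSeries(table.start, total),
    )


def _strategy_pool(table: CommunityTable, strategy: str) -> list[str]:
    if strategy == "random":
        return sorted(table.taxon_ids)
    if strategy.startswith("functional_group:"):
        group = strategy.split(":", 1)[1]
        if group not in FUNCTIONAL_GROUPS or group == "other":
            # singleton catch-all categories are excluded from group analyses
            raise InvalidStrategyError(f"invalid strategy: {strategy!r}")
        return table.group_pool(group)
    if strategy.startswith("size_class:"):
        klass = strategy.split(":", 1)[1]
        if klass not in SIZE_CLASSES:
            raise InvalidStrategyError(f"invalid strategy: {strategy!r}")
        return table.size_class_pool(klass)
    raise InvalidStrategyError(f"invalid strategy: {strategy!r}")


def sample_assemblages(
    table: CommunityTable,
    size: int,
    n_trials: int,
    strategy: str = "random",
    rng_seed: int = 0,
) -> list[Assemblage]:
    """Draw ``n_trials`` random assemblages of ``size`` distinct taxa.

    Strategies: ``"random"`` (whole community),
    ``"functional_group:<g>"`` (g in diatom / dinoflagellate /
    coccolithophore / phytoflagellate), ``"size_class:<c>"`` (c in
    small / medium / large, radius <5 / 5-12 / >12 um).  Trials are
    independent uniform draws without replacement within a trial, so every
    pool member has equal inclusion probability and combinations may repeat
    across trials.
    """
    pool = _strategy_pool(table, strategy)
    if size < 1:
        raise EmptyAssemblageError("assemblage size must be >= 1")
    if size > len(pool):
        raise PoolExhaustedError(
            f"pool exhausted: size {size} > pool {len(pool)} for {strategy!r}"
        )
    out = []
    pool_arr = np.array(pool)
    for j in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence((rng_seed, size, j)))
        members = rng.choice(pool_arr, size=size, replace=False)
        out.append(aggregate(table, list(members)))
    return out


def predictability_curve(
    table: CommunityTable,
    sizes: Sequence[int],
    n_trials: int,
    n_surrogates: int = 0,
    config: EmbeddingConfig | None = None,
    rng_seed: int = 0,
    strategy: str = "random",
) -> list[TrialSummary]:
    """Mean simplex skill versus assemblage size.

    For each size, draws ``n_trials`` assemblages, forecasts each aggregate
    with embedding-dimension selection, and (optionally) forecasts
    ``n_surrogates`` seasonal surrogates per trial.  Trials whose forecast is
    degenerate are excluded from the mean and counted in ``n_failed``.
    """
    cfg = config or EmbeddingConfig()
    summaries = []
    for size in sizes:
        assemblages = sample_assemblages(table, size, n_trials, strategy, rng_seed)
        rhos, sur_means = [], []
        n_failed = 0
        for j, asm in enumerate(assemblages):
            try:
                rhos.append(select_embedding(asm.series, cfg).rho)
            except (SeriesUnusableError, UndefinedCorrelationError):
                n_failed += 1
                continue
            if n_surrogates > 0:
                sub = np.random.SeedSequence((rng_seed, size, j, 1))
                sur_seed = int(sub.generate_state(1)[0] & 0x7FFFFFFF)
                sur_means.append(
                    surrogate_skill(asm.series, n_surrogates, cfg, sur_seed).mean_rho
                )
        if rhos:
            arr = np.asarray(rhos)
            se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
            summaries.append(
                TrialSummary(
                    assemblage_size=int(size),
                    strategy=strategy,
                    n_trials=arr.size,
                    mean_rho=float(arr.mean()),
                    se=se,
                    ci95_half_width=1.96 * se,
                    mean_surrogate_rho=(
                        float(np.nanmean(sur_means)) if sur_means else None
                    ),
                    n_failed=n_failed,
                )
            )
        else:
            summaries.append(
                TrialSummary(
                    assemblage_size=int(size),
                    strategy=strategy,
                    n_trials=0,
                    mean_rho=float("nan"),
                    se=float("nan"),
                    ci95_half_width=float("nan"),
                    n_failed=n_failed,
                    valid=False,
                )
            )
    return summaries


def coefficient_of_variation(assemblage: Assemblage | MonthlyTimeSeries) -> float:
    """Sample SD over mean of the non-missing months of an aggregate.

    The portfolio-effect diagnostic: aggregates of many imperfectly
    correlated members have lower CV than their members.
    """
    series = assemblage.series if isinstance(assemblage, Assemblage) else assemblage
    vals = series.values[series.observed_mask]
    if vals.size < 2:
        raise UndefinedCVError("need >= 2 non-missing months")
    mean = vals.mean()
    if mean == 0:
        raise UndefinedCVError("undefined CV: zero mean")
    return float(vals.std(ddof=1) / mean)


def exclusion_filter(
    table: CommunityTable,
    criterion: str,
    fraction: float,
    config: EmbeddingConfig | None = None,
) -> CommunityTable:
    """Drop the top ``fraction`` of taxa by abundance or by predictability.

    ``criterion="abundance"`` ranks by mean non-missing abundance;
    ``criterion="predictability"`` ranks by simplex skill with embedding
    selection (a taxon whose forecast fails ranks below all that succeed).
    The top ``ceil(fraction * N)`` are removed; ranking ties break by taxon
    id.  Used to test whether the skill-vs-size rise survives removing the
    dominant or most predictable species.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if criterion == "abundance":
        def score(rec):
            vals = rec.series.values[rec.series.observed_mask]
            return float(vals.mean()) if vals.size else float("-inf")
    elif criterion == "predictability":
        cfg = config or EmbeddingConfig()

        def score(rec):
            try:
                return select_embedding(rec.series, cfg).rho
            except (SeriesUnusableError, UndefinedCorrelationError):
                return float("-inf")
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    ranked = sorted(table, key=lambda rec: (-score(rec), rec.taxon_id))
    n_remove = math.ceil(fraction * len(table))
    if n_remove >= len(table):
        raise FilterTooAggressiveError("filter too aggressive: no taxa remain")
    keep = {rec.taxon_id for rec in ranked[n_remove:]}
    return table.subset(keep)
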