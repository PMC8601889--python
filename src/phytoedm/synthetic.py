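"""Synthetic coastal-station community generator.

Builds a community table with the shape of a long-term coastal phytoplankton
monitoring record: 198 taxa (130 diatoms, 37 dinoflagellates, 16
coccolithophores, 14 phytoflagellates, 1 other) on a 267-month grid
(Oct 1992 - Dec 2014) with 10 shared missing months, annually recurring
blooms of taxon-specific timing and sharpness, mean abundances spread over
several orders of magnitude, and multiplicative lognormal noise.

The generator reproduces the *statistical shape* of such a record — taxon
composition, size-class partition, seasonality, scale heterogeneity,
shared sampling gaps — not any real taxon's abundances.  Gaps are shared
across taxa because a missed cruise affects every count in the sample.

Each taxon's latent abundance is

    b_i(t) = scale_i * exp(kappa_i * (cos(2 pi (t - peak_i) / 12) - 1))
    x_i(t) = b_i(t) * exp(sigma_i * z_t - sigma_i^2 / 2),   z ~ N(0, 1)

a von-Mises-like annual bloom with sharpness kappa, under mean-preserving
lognormal noise: counts stay positive and right-skewed, and rare taxa remain
intermittent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .timeseries import CommunityTable, MonthlyTimeSeries, TaxonRecord

__all__ = ["SyntheticL4Config", "generate_l4_like", "inject_predictability_gradient"]

_GROUP_COUNTS = {
    "diatom": 130,
    "dinoflagellate": 37,
    "coccolithophore": 16,
    "phytoflagellate": 14,
    "other": 1,
}
_SIZE_CLASS_COUNTS = {"small": 68, "medium": 63, "large": 67}
_DIATOM_SIZE_COUNTS = {"small": 44, "medium": 40, "large": 46}
# radii drawn uniformly inside each bucket, clear of the 5 / 12 um boundaries
_RADIUS_RANGES = {"small": (0.5, 4.5), "medium": (5.0, 12.0), "large": (12.5, 60.0)}


@dataclass(frozen=True)
class SyntheticL4Config:
    """Composition and statistical shape of the generated community."""

    group_counts: dict = field(default_factory=lambda: dict(_GROUP_COUNTS))
    size_class_counts: dict = field(
        default_factory=lambda: dict(_SIZE_CLASS_COUNTS)
    )
    diatom_size_counts: dict = field(
        default_factory=lambda: dict(_DIATOM_SIZE_COUNTS)
    )
    start: tuple[int, int] = (1992, 10)
    n_months: int = 267  # Oct 1992 .. Dec 2014 inclusive
    n_missing_months: int = 10
    scale_log10_range: tuple[float, float] = (1.0, 5.0)  # cells L^-1, log10
    bloom_sharpness_range: tuple[float, float] = (0.5, 3.0)
    noise_sigma_range: tuple[float, float] = (0.3, 1.0)
    # bloom timing clusters in a shared productive season (calendar-month
    # index, 0 = January): temperate coastal communities bloom coherently
    # in spring-summer, which is what lets aggregates reinforce a common
    # seasonal signal while taxon-level noise cancels
    bloom_month_mean: float = 4.5
    bloom_month_sd: float = 2.0
    rng_seed: int = 0

    @property
    def n_taxa(self) -> int:
        return sum(self.group_counts.values())

    def validate(self) -> None:
        n = self.n_taxa
        if sum(self.size_class_counts.values()) != n:
            raise ValueError("size_class_counts must sum to n_taxa")
        n_diatom = self.group_counts.get("diatom", 0)
        if sum(self.diatom_size_counts.values()) != n_diatom:
            raise ValueError("diatom_size_counts must sum to the diatom count")
        for k in self.diatom_size_counts:
            if self.diatom_size_counts[k] > self.size_class_counts[k]:
                raise ValueError(f"diatom size count exceeds total for {k!r}")
        if self.n_missing_months >= self.n_months:
            raise ValueError("n_missing_months must be < n_months")


def _seasonal_baseline(
    n_months: int, start_month: int, scale: float, kappa: float, peak: float
) -> np.ndarray:
    t = (start_month - 1 + np.arange(n_months)) % 12
    return scale * np.exp(kappa * (np.cos(2 * math.pi * (t - peak) / 12) - 1.0))


def generate_l4_like(config: SyntheticL4Config | None = None) -> CommunityTable:
    """Generate a seeded, fully reproducible community table.

    Taxon ids are ``tax000..tax197``, assigned group labels in the configured
    counts; radii are drawn inside each size bucket so the size-class
    partition matches the configured counts exactly, including the diatom
    sub-partition.  The same ``n_missing_months`` months are missing in every
    series.
    """
    cfg = config or SyntheticL4Config()
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.rng_seed,)))

    groups: list[str] = []
    for g, cnt in cfg.group_counts.items():
        groups.extend([g] * cnt)

    # size classes: diatoms fill their configured sub-partition, the
    # remaining bucket capacity is distributed randomly over non-diatoms
    classes = [""] * cfg.n_taxa
    diatom_idx = [i for i, g in enumerate(groups) if g == "diatom"]
    other_idx = [i for i, g in enumerate(groups) if g != "diatom"]
    diatom_labels: list[str] = []
    for k, cnt in cfg.diatom_size_counts.items():
        diatom_labels.extend([k] * cnt)
    rng.shuffle(diatom_labels)
    for i, lab in zip(diatom_idx, diatom_labels):
        classes[i] = lab
    rest_labels: list[str] = []
    for k in cfg.size_class_counts:
        rest_labels.extend([k] * (cfg.size_class_counts[k] - cfg.diatom_size_counts.get(k, 0)))
    rng.shuffle(rest_labels)
    for i, lab in zip(other_idx, rest_labels):
        classes[i] = lab

    missing = rng.choice(cfg.n_months, size=cfg.n_missing_months, replace=False)

    taxa = []
    for i in range(cfg.n_taxa):
        lo, hi = _RADIUS_RANGES[classes[i]]
        radius = float(rng.uniform(lo, hi))
        scale = 10.0 ** rng.uniform(*cfg.scale_log10_range)
        kappa = rng.uniform(*cfg.bloom_sharpness_range)
        peak = (cfg.bloom_month_mean + cfg.bloom_month_sd * rng.standard_normal()) % 12
        sigma = rng.uniform(*cfg.noise_sigma_range)
        baseline = _seasonal_baseline(
            cfg.n_months, cfg.start[1], scale, kappa, peak
        )
        z = rng.standard_normal(cfg.n_months)
        values = baseline * np.exp(sigma * z - sigma**2 / 2)
        values[missing] = np.nan
        taxa.append(
            TaxonRecord(
                taxon_id=f"tax{i:03d}",
                functional_group=groups[i],
                cell_radius=radius,
                series=MonthlyTimeSeries(cfg.start, values),
            )
        )
    return CommunityTable(taxa)


def inject_predictability_gradient(
    table: CommunityTable,
    fraction_predictable: float,
    rng_seed: int = 0,
) -> tuple[CommunityTable, dict[str, bool]]:
    """Replace taxon dynamics with a known predictability split.

    A random ``fraction_predictable`` of taxa become low-noise, sharply
    seasonal signals (high simplex skill); the rest become noisy signals
    whose weaker seasonal component is swamped by lognormal variability
    (low skill).  Bloom months cluster in the shared productive season for
    both classes.  Each taxon keeps its mean abundance level, group, and
    radius, and the table's missing months are preserved.
    Returns the new table and the ground-truth labels
    (``taxon_id -> True`` if predictable), so ranking-based filters can be
    validated against known labels.
    """
    if not 0 <= fraction_predictable <= 1:
        raise ValueError("fraction_predictable must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed,)))
    ids = table.taxon_ids
    n_pred = int(round(fraction_predictable * len(ids)))
    chosen = set(rng.choice(np.array(ids), size=n_pred, replace=False))
    n_months = table.n_months
    start_month = table.start[1]

    taxa = []
    labels = {}
    for rec in table:
        predictable = rec.taxon_id in chosen
        labels[rec.taxon_id] = predictable
        obs = rec.series.values[rec.series.observed_mask]
        scale = float(obs.mean()) if obs.size else 1.0
        peak = (4.5 + 2.0 * rng.standard_normal()) % 12
        if predictable:
            kappa, sigma = 2.0, 0.1
        else:
            kappa, sigma = rng.uniform(0.5, 1.5), 1.2
        baseline = _seasonal_baseline(n_months, start_month, scale, kappa, peak)
        z = rng.standard_normal(n_months)
        values = baseline * np.exp(sigma * z - sigma**2 / 2)
        values[~rec.series.observed_mask] = np.nan
        taxa.append(
            TaxonRecord(
                taxon_id=rec.taxon_id,
                functional_group=rec.functional_group,
                cell_radius=rec.cell_radius,
                series=MonthlyTimeSeries(table.start, values),
            )
        )
    return CommunityTable(taxa), labels
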