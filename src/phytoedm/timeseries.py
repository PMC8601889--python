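"""Core containers: monthly abundance series and the community table.

A :class:`MonthlyTimeSeries` is one abundance record (cells L^-1) on a strictly
consecutive monthly grid.  Missing months are explicit ``NaN`` entries, never
implicit gaps: the grid always runs from ``start`` for ``len(values)`` months.

A :class:`CommunityTable` is the collection of per-taxon records (series plus
functional group and cell radius) that every downstream experiment consumes;
all member series share one grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

FUNCTIONAL_GROUPS = frozenset(
    {"diatom", "dinoflagellate", "coccolithophore", "phytoflagellate", "other"}
)

MISSING = float("nan")


def _as_year_month(start: tuple[int, int]) -> tuple[int, int]:
    year, month = int(start[0]), int(start[1])
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return year, month


@dataclass
class MonthlyTimeSeries:
    """One abundance series on a regular monthly grid.

    Parameters
    ----------
    start
        ``(year, month)`` of the first grid cell, month in 1..12.
    values
        Abundances, one per consecutive month; ``NaN`` marks a missing month.
        Non-missing values must be >= 0 (cell densities).
    """

    start: tuple[int, int]
    values: np.ndarray
    # derived series (e.g. seasonal surrogates, whose shuffled anomalies can
    # undershoot the climatology) may carry negative values; measured
    # abundances may not
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.start = _as_year_month(self.start)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        observed = self.values[~np.isnan(self.values)]
        if not self.allow_negative and observed.size and observed.min() < 0:
            raise ValueError("abundances must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def calendar_months(self) -> np.ndarray:
        """Calendar month (1..12) of every grid position."""
        first = self.start[1] - 1
        return (first + np.arange(len(self))) % 12 + 1

    def month_labels(self) -> list[str]:
        """ISO ``YYYY-MM`` labels for the grid."""
        year, month = self.start
        labels = []
        for _ in range(len(self)):
            labels.append(f"{year:04d}-{month:02d}")
            month += 1
            if month == 13:
                month = 1
                year += 1
        return labels

    def copy_with(
        self, values: np.ndarray, allow_negative: bool | None = None
    ) -> "MonthlyTimeSeries":
        if allow_negative is None:
            allow_negative = self.allow_negative
        return MonthlyTimeSeries(
            self.start, np.asarray(values, dtype=float), allow_negative
        )


@dataclass
class TaxonRecord:
    """One taxon: id, functional group, cell radius (um), abundance series."""

    taxon_id: str
    functional_group: str
    cell_radius: float
    series: MonthlyTimeSeries

    def __post_init__(self) -> None:
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise ValueError(
                f"unknown functional group {self.functional_group!r}; "
                f"expected one of {sorted(FUNCTIONAL_GROUPS)}"
            )
        if not self.cell_radius > 0:
            raise ValueError("cell_radius must be positive")


# size-class boundaries (um, cell radius); the middle class is inclusive
SIZE_CLASS_SMALL = "small"    # radius < 5
SIZE_CLASS_MEDIUM = "medium"  # 5 <= radius <= 12
SIZE_CLASS_LARGE = "large"    # radius > 12
SIZE_CLASSES = (SIZE_CLASS_SMALL, SIZE_CLASS_MEDIUM, SIZE_CLASS_LARGE)


def size_class(radius: float) -> str:
    """Bucket a cell radius into small (<5 um), medium (5-12 um), large (>12 um)."""
    if radius < 5:
        return SIZE_CLASS_SMALL
    if radius <= 12:
        return SIZE_CLASS_MEDIUM
    return SIZE_CLASS_LARGE


@dataclass
class CommunityTable:
    """A collection of taxa sharing one monthly grid."""

    taxa: list[TaxonRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.taxa:
            return
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon ids")
        ref = self.taxa[0].series
        for t in self.taxa[1:]:
            if t.series.start != ref.start or len(t.series) != len(ref):
                raise ValueError(
                    f"taxon {t.taxon_id!r} is not on the shared monthly grid"
                )
        self._by_id = {t.taxon_id: t for t in self.taxa}

    def __len__(self) -> int:
        return len(self.taxa)

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self.taxa)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._by_id

    def __getitem__(self, taxon_id: str) -> TaxonRecord:
        return self._by_id[taxon_id]

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    @property
    def start(self) -> tuple[int, int]:
        return self.taxa[0].series.start

    @property
    def n_months(self) -> int:
        return len(self.taxa[0].series)

    def subset(self, taxon_ids: Sequence[str]) -> "CommunityTable":
        """New table restricted to ``taxon_ids`` (original order preserved)."""
        keep = set(taxon_ids)
        return CommunityTable([t for t in self.taxa if t.taxon_id in keep])

    def group_pool(self, group: str) -> list[str]:
        """Sorted ids of all taxa in a functional group."""
        return sorted(t.taxon_id for t in self.taxa if t.functional_group == group)

    def size_class_pool(self, klass: str) -> list[str]:
        """Sorted ids of all taxa whose radius falls in a size class."""
        return sorted(
            t.taxon_id for t in self.taxa if size_class(t.cell_radius) == klass
        )
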