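"""Readers and writers for community tables and experiment results.

On-disk layout (all comma-separated, UTF-8, "." decimal):

* abundance CSV — wide, taxa x months; first column ``taxon_id``, remaining
  headers ISO ``YYYY-MM`` labels of strictly consecutive months; an empty
  cell is a missing month (zero is a legitimate abundance and is written as
  ``0``).
* metadata CSV — columns ``taxon_id, functional_group, cell_radius_um``.
* results CSV — tidy, one row per (size, strategy):
  ``size, strategy, n_trials, mean_rho, se, ci95_half_width,
  mean_surrogate_rho, n_failed``.

Floats are written with Python's shortest round-tripping repr, so a write /
read cycle reproduces values bit-exactly.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assemblage import TrialSummary
from .errors import (
    BrokenGridError,
    InvalidMetadataError,
    InvalidValueError,
    MalformedTableError,
)
from .timeseries import (
    FUNCTIONAL_GROUPS,
    CommunityTable,
    MonthlyTimeSeries,
    TaxonRecord,
)

__all__ = [
    "read_community_csv",
    "write_community_csv",
    "write_results",
    "read_results",
]


def _parse_month_headers(headers: Sequence[str]) -> tuple[int, int]:
    """Validate strictly consecutive ``YYYY-MM`` headers; return the start."""
    try:
        periods = [pd.Period(h, freq="M") for h in headers]
    except Exception as exc:  # noqa: BLE001 - any parse failure is a grid error
        raise BrokenGridError(f"broken grid: unparseable month header ({exc})")
    for prev, cur in zip(periods, periods[1:]):
        if cur != prev + 1:
            raise BrokenGridError(
                f"broken grid: {prev} is not followed by {prev + 1} (got {cur})"
            )
    first = periods[0]
    return int(first.year), int(first.month)


def read_community_csv(
    abundance_path: str | Path, metadata_path: str | Path
) -> CommunityTable:
    """Load and validate a community table from abundance + metadata CSVs."""
    try:
        wide = pd.read_csv(abundance_path, index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise MalformedTableError(f"malformed table: {exc}")
    if wide.isnull().values.any(axis=None) and wide.columns.size == 0:
        raise MalformedTableError("malformed table: no month columns")
    start = _parse_month_headers(list(wide.columns))

    values = np.full(wide.shape, np.nan)
    for i, (_, row) in enumerate(wide.iterrows()):
        for j, cell in enumerate(row):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            text = str(cell).strip()
            if text == "":
                continue
            try:
                v = float(text)
            except ValueError:
                raise InvalidValueError(f"invalid value {text!r}")
            if v < 0:
                raise InvalidValueError(f"invalid value: negative abundance {v}")
            values[i, j] = v

    meta = pd.read_csv(metadata_path)
    required = {"taxon_id", "functional_group", "cell_radius_um"}
    if not required.issubset(meta.columns):
        raise InvalidMetadataError(
            f"invalid metadata: need columns {sorted(required)}"
        )
    meta = meta.set_index("taxon_id")
    abundance_ids = list(wide.index.astype(str))
    if set(abundance_ids) != set(meta.index.astype(str)):
        raise InvalidMetadataError(
            "invalid metadata: taxon ids do not match the abundance table"
        )

    taxa = []
    for i, taxon_id in enumerate(abundance_ids):
        group = str(meta.loc[taxon_id, "functional_group"])
        if group not in FUNCTIONAL_GROUPS:
            raise InvalidMetadataError(f"invalid metadata: unknown group {group!r}")
        radius = float(meta.loc[taxon_id, "cell_radius_um"])
        if not radius > 0:
            raise InvalidMetadataError("invalid metadata: cell radius must be > 0")
        taxa.append(
            TaxonRecord(
                taxon_id=taxon_id,
                functional_group=group,
                cell_radius=radius,
                series=MonthlyTimeSeries(start, values[i]),
            )
        )
    return CommunityTable(taxa)


def write_community_csv(
    table: CommunityTable,
    abundance_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write a community table as the standard abundance + metadata CSVs."""
    labels = table.taxa[0].series.month_labels()
    with open(abundance_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("taxon_id," + ",".join(labels) + "\n")
        for rec in table:
            cells = [
                "" if np.isnan(v) else repr(float(v)) for v in rec.series.values
            ]
            fh.write(rec.taxon_id + "," + ",".join(cells) + "\n")
    with open(metadata_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("taxon_id,functional_group,cell_radius_um\n")
        for rec in table:
            fh.write(
                f"{rec.taxon_id},{rec.functional_group},{rec.cell_radius!r}\n"
            )


_RESULT_COLUMNS = [
    "size",
    "strategy",
    "n_trials",
    "mean_rho",
    "se",
    "ci95_half_width",
    "mean_surrogate_rho",
    "n_failed",
]


def write_results(summaries: Sequence[TrialSummary], path: str | Path) -> None:
    """Write trial summaries as a tidy CSV (one row per size x strategy)."""
    if not summaries:
        raise ValueError("no summaries to write")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_RESULT_COLUMNS) + "\n")
        for s in summaries:
            sur = "" if s.mean_surrogate_rho is None else repr(s.mean_surrogate_rho)
            fh.write(
                f"{s.assemblage_size},{s.strategy},{s.n_trials},"
                f"{s.mean_rho!r},{s.se!r},{s.ci95_half_width!r},{sur},"
                f"{s.n_failed}\n"
            )


def read_results(path: str | Path) -> list[TrialSummary]:
    """Read back a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        sur = row["mean_surrogate_rho"]
        out.append(
            TrialSummary(
                assemblage_size=int(row["size"]),
                strategy=str(row["strategy"]),
                n_trials=int(row["n_trials"]),
                mean_rho=float(row["mean_rho"]),
                se=float(row["se"]),
                ci95_half_width=float(row["ci95_half_width"]),
                mean_surrogate_rho=None if pd.isna(sur) else float(sur),
                n_failed=int(row["n_failed"]),
                valid=int(row["n_trials"]) > 0,
            )
        )
    return out
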