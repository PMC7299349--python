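"""Live/dead cell-viability estimation from two-channel fluorescence.

Segmented regions from stained micrographs carry a classifier region
score (-50..50); only regions scored between 25 and 50 — i.e.
P(Cell) > 75% — are kept as cells. A cell is scored dead when its red
(dead-stain) fluorescence strictly exceeds its green (live-stain)
fluorescence. The overall mortality of a strain is the proportion of
dead cells pooled over replicate cultures (weighting each replicate by
the number of cells analyzed), with a BCa bootstrap interval that
resamples replicate cultures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import BootstrapConfig, bca_interval

__all__ = [
    "CellRecord",
    "ViabilitySummary",
    "filter_cells",
    "classify_dead",
    "mortality_summary",
]


@dataclass(frozen=True)
class CellRecord:
    """One segmented region: classifier score plus two-channel fluorescence."""

    replicate_id: str
    region_score: float  # in [-50, 50]
    green: float  # live-stain channel, arbitrary units >= 0
    red: float  # dead-stain channel, arbitrary units >= 0

    def __post_init__(self) -> None:
        if not -50.0 <= self.region_score <= 50.0:
            raise ValueError("region_score must lie in [-50, 50]")
        if self.green < 0 or self.red < 0:
            raise ValueError("fluorescence must be non-negative")


@dataclass(frozen=True)
class ViabilitySummary:
    """Replicate-level and overall dead-cell proportions."""

    per_replicate: pd.DataFrame  # columns: replicate_id, n_cells, n_dead, proportion
    overall: float  # sum(dead) / sum(cells) across replicates
    ci: Optional[tuple[float, float]]  # BCa interval, None for a single replicate


def filter_cells(
    cells: Sequence[CellRecord], score_min: float = 25.0, score_max: float = 50.0
) -> list[CellRecord]:
    """Keep regions confidently classified as cells (score in [25, 50])."""
    return [c for c in cells if score_min <= c.region_score <= score_max]


def classify_dead(cell: CellRecord) -> bool:
    """Dead iff red fluorescence strictly exceeds green (tie -> alive)."""
    return cell.red > cell.green


def mortality_summary(
    cells: Sequence[CellRecord],
    boot: BootstrapConfig = BootstrapConfig(),
    resample: str = "replicate",
) -> ViabilitySummary:
    """Weighted mortality estimate with a BCa bootstrap interval.

    The overall proportion pools cells across replicates,
    sum(dead) / sum(cells) — identical to the cell-count-weighted mean
    of replicate proportions. The interval resamples replicate cultures
    and recomputes the weighted proportion per resample; with a single
    replicate only the point estimate is returned. ``resample='cell'``
    instead resamples cells within the pooled data (non-default).
    """
    if not cells:
        raise ValueError("no cells to summarize")
    df = pd.DataFrame(
        {
            "replicate_id": [c.replicate_id for c in cells],
            "dead": [classify_dead(c) for c in cells],
        }
    )
    per = (
        df.groupby("replicate_id")["dead"]
        .agg(n_cells="size", n_dead="sum")
        .reset_index()
    )
    per["proportion"] = per["n_dead"] / per["n_cells"]
    overall = float(per["n_dead"].sum() / per["n_cells"].sum())

    ci: Optional[tuple[float, float]] = None
    if resample == "cell":
        ci = bca_interval(df["dead"].to_numpy(dtype=float), boot)
    elif len(per) >= 2:
        ci = bca_interval(
            per["proportion"].to_numpy(),
            boot,
            weights=per["n_cells"].to_numpy(dtype=float),
        )
    return ViabilitySummary(per_replicate=per, overall=overall, ci=ci)
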