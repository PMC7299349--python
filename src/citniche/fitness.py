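"""Competition-assay relative fitness from colony counts.

Two competitors distinguished by an arabinose marker are plated at the
start and end of a serial-transfer competition. Each competitor's
Malthusian parameter is its realized net growth ln(final/initial
density) plus the expansion implied by the (duration - 1) hundred-fold
serial transfers; relative fitness W is the ratio of the test
competitor's Malthusian parameter to the reference's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PlateCount",
    "CompetitionAssay",
    "FitnessResult",
    "density",
    "pooled_density",
    "malthusian",
    "relative_fitness",
    "summarize_fitness",
]


@dataclass(frozen=True)
class PlateCount:
    """Colonies of one competitor on one dilution plate."""

    competitor_id: str
    marker: str  # "Ara+" or "Ara-"
    dilution_factor: float  # e.g. 1e4 for the 10^-4 plate
    volume_ml: float  # plated volume, e.g. 0.1 mL
    colonies: int

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colonies must be non-negative")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be positive")

    @property
    def usable(self) -> bool:
        """Zero-colony plates cannot anchor a log density."""
        return self.colonies > 0


@dataclass(frozen=True)
class CompetitionAssay:
    """Paired initial/final plate counts for both competitors of one replicate.

    ``initial`` and ``final`` map competitor role ("test" / "reference")
    to the plate counts for that competitor at that time point (possibly
    several countable dilutions).
    """

    replicate_id: str
    duration_days: int
    transfer_dilution: float  # fold-dilution at each serial transfer (100 in DM)
    initial: dict[str, list[PlateCount]]
    final: dict[str, list[PlateCount]]

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        for point in (self.initial, self.final):
            for role in ("test", "reference"):
                if role not in point:
                    raise ValueError(f"missing counts for role '{role}'")


@dataclass(frozen=True)
class FitnessResult:
    """Relative fitness of one competition replicate."""

    replicate_id: str
    W: float
    m_test: float
    m_ref: float


def density(count: PlateCount) -> Optional[float]:
    """CFU per mL implied by one plate: colonies x dilution / volume.

    Returns None (unusable) for zero-colony plates; the caller must
    exclude them or fall back to another countable dilution.
    """
    if not count.usable:
        return None
    return count.colonies * count.dilution_factor / count.volume_ml


def pooled_density(counts: Sequence[PlateCount]) -> Optional[float]:
    """Combine countable dilutions of one culture.

    Per-plate densities are averaged weighted by colony count, so the
    better-counted plate dominates. None if no plate is usable.
    """
    dens, weights = [], []
    for c in counts:
        d = density(c)
        if d is not None:
            dens.append(d)
            weights.append(c.colonies)
    if not dens:
        return None
    return float(np.average(dens, weights=weights))


def malthusian(
    n0: float, nf: float, duration_days: int, transfer_dilution: float = 100.0
) -> float:
    """Malthusian parameter over the whole assay, dilutions included.

    m = ln( nf * D^(d-1) / n0 ): the cumulative net expansion of the
    competitor, where the factor D^(d-1) restores the (d - 1) serial
    transfers at D-fold dilution. For a one-day assay this reduces to
    ln(nf / n0).
    """
    if n0 <= 0 or nf <= 0:
        raise ValueError("densities must be positive")
    if duration_days < 1:
        raise ValueError("duration_days must be >= 1")
    return math.log(nf * transfer_dilution ** (duration_days - 1) / n0)


def relative_fitness(assay: CompetitionAssay) -> FitnessResult:
    """Relative fitness W = m_test / m_ref for one replicate.

    Raises if any density is unusable or the reference did not grow
    (m_ref <= 0), in which case W is undefined.
    """
    dens = {}
    for point_name, point in (("initial", assay.initial), ("final", assay.final)):
        for role in ("test", "reference"):
            d = pooled_density(point[role])
            if d is None:
                raise ValueError(
                    f"unusable (zero-colony) counts for {role} at {point_name} "
                    f"in replicate {assay.replicate_id}"
                )
            dens[(point_name, role)] = d
    m_test = malthusian(
        dens[("initial", "test")],
        dens[("final", "test")],
        assay.duration_days,
        assay.transfer_dilution,
    )
    m_ref = malthusian(
        dens[("initial", "reference")],
        dens[("final", "reference")],
        assay.duration_days,
        assay.transfer_dilution,
    )
    if m_ref <= 0:
        raise ValueError("reference competitor did not grow; W undefined")
    return FitnessResult(assay.replicate_id, W=m_test / m_ref, m_test=m_test, m_ref=m_ref)


def summarize_fitness(
    results: Sequence[FitnessResult], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Mean W across replicates with its t-distributed confidence interval.

    Returns (mean, (lower, upper)) with the usual
    mean +/- t_{1-alpha/2, n-1} * SE interval. Requires >= 2 replicates.
    """
    ws = np.array([r.W for r in results], dtype=float)
    n = ws.size
    if n < 2:
        raise ValueError("summarize_fitness requires at least 2 replicates")
    mean = float(ws.mean())
    se = float(ws.std(ddof=1) / math.sqrt(n))
    half = float(sps.t.ppf(1 - alpha / 2, n - 1)) * se
    return mean, (mean - half, mean + half)
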