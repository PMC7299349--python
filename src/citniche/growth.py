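"""Growth-curve kinetics by the log-slope method.

Exponential growth rates are estimated as ordinary-least-squares slopes
of ln(OD420) versus time inside fixed OD windows — [0.01, 0.02] for the
glucose phase and [0.05, 0.10] for the citrate phase of a diauxic curve
— and lag time as the first crossing of OD 0.01. Measurements before
t_min (default 30 min) are discarded. In citrate-only (DM0) medium only
lag and the citrate rate are estimated; in glucose+citrate (DM25) medium
all three parameters are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .stats import BootstrapConfig, bca_interval

__all__ = [
    "ODCurve",
    "GrowthConfig",
    "GrowthFit",
    "estimate_rate",
    "estimate_lag",
    "fit_growth",
    "bootstrap_growth",
    "log2_ratio",
    "PARAMETERS",
]

PARAMETERS = ("r_glucose", "r_citrate", "lag_h")


@dataclass(frozen=True)
class ODCurve:
    """One well's OD420 time series."""

    sample_id: str
    well_id: str
    medium: str  # "DM0" (citrate only) or "DM25" (glucose + citrate)
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # OD420, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        o = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", o)
        if t.shape != o.shape or t.ndim != 1:
            raise ValueError("times and od must be 1-D and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.medium not in ("DM0", "DM25"):
            raise ValueError("medium must be 'DM0' or 'DM25'")


@dataclass(frozen=True)
class GrowthConfig:
    """Windows and thresholds of the log-slope method.

    glucose_window / citrate_window are OD420 intervals; lag_threshold is
    the OD whose first crossing defines the lag; observations before
    t_min hours are discarded; a rate needs at least min_points in-window
    observations. blank is a constant OD subtracted from every reading
    (0 = raw OD, the default).
    """

    glucose_window: tuple[float, float] = (0.01, 0.02)
    citrate_window: tuple[float, float] = (0.05, 0.10)
    lag_threshold: float = 0.01
    t_min: float = 0.5
    min_points: int = 2
    blank: float = 0.0

    def __post_init__(self) -> None:
        for lo, hi in (self.glucose_window, self.citrate_window):
            if not lo < hi:
                raise ValueError("window lower bound must be below upper bound")
        if self.lag_threshold <= 0:
            raise ValueError("lag_threshold must be positive")


@dataclass(frozen=True)
class GrowthFit:
    """Per-curve growth parameters; None marks an inestimable parameter."""

    r_glucose: Optional[float]
    r_citrate: Optional[float]
    lag_h: Optional[float]
    n_points_glucose: int = 0
    n_points_citrate: int = 0

    def parameter(self, name: str) -> Optional[float]:
        return getattr(self, name)


def _retained(curve: ODCurve, config: GrowthConfig) -> tuple[np.ndarray, np.ndarray]:
    keep = curve.times >= config.t_min
    od = curve.od[keep] - config.blank
    return curve.times[keep], od


def _first_run(mask: np.ndarray) -> slice:
    """Slice of the first maximal contiguous run of True, or empty slice."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return slice(0, 0)
    start = idx[0]
    end = start
    while end + 1 < mask.size and mask[end + 1]:
        end += 1
    return slice(start, end + 1)


def estimate_rate(
    curve: ODCurve, window: tuple[float, float], config: GrowthConfig
) -> Optional[float]:
    """OLS slope of ln(OD) vs time over the first in-window run (per hour).

    Restricts to t >= t_min, takes the first maximal contiguous run of
    points with OD inside ``window``, and regresses ln(OD) on time.
    Returns None when fewer than ``config.min_points`` points fall in
    the run (the parameter could not be estimated accurately).
    """
    t, od = _retained(curve, config)
    lo, hi = window
    run = _first_run((od >= lo) & (od <= hi))
    t_run, od_run = t[run], od[run]
    if t_run.size < max(config.min_points, 2):
        return None
    slope = sps.linregress(t_run, np.log(od_run)).slope
    return float(slope)


def estimate_lag(curve: ODCurve, config: GrowthConfig) -> Optional[float]:
    """First time (t >= t_min) at which OD reaches the lag threshold, in hours.

    Linearly interpolates between the bracketing observations to remove
    the sampling-interval quantization; if the first retained
    observation is already at or above threshold, its (t_min-censored)
    time is returned. Returns None when the threshold is never reached.
    """
    t, od = _retained(curve, config)
    thr = config.lag_threshold
    above = np.flatnonzero(od >= thr)
    if above.size == 0:
        return None
    i = above[0]
    if i == 0:
        return float(t[0])
    t0, t1 = t[i - 1], t[i]
    o0, o1 = od[i - 1], od[i]
    if o1 == o0:
        return float(t1)
    return float(t0 + (thr - o0) * (t1 - t0) / (o1 - o0))


def fit_growth(curve: ODCurve, config: GrowthConfig = GrowthConfig()) -> GrowthFit:
    """Estimate all growth parameters for one well.

    The glucose rate is only defined for DM25 curves (DM0 has no glucose
    phase); lag and the citrate rate are estimated in both media.
    Inestimable components propagate as None without failing the fit.
    """
    t, od = _retained(curve, config)

    def _n_in(window: tuple[float, float]) -> int:
        run = _first_run((od >= window[0]) & (od <= window[1]))
        return run.stop - run.start

    r_glu = (
        estimate_rate(curve, config.glucose_window, config)
        if curve.medium == "DM25"
        else None
    )
    r_cit = estimate_rate(curve, config.citrate_window, config)
    return GrowthFit(
        r_glucose=r_glu,
        r_citrate=r_cit,
        lag_h=estimate_lag(curve, config),
        n_points_glucose=_n_in(config.glucose_window) if curve.medium == "DM25" else 0,
        n_points_citrate=_n_in(config.citrate_window),
    )


def bootstrap_growth(
    replicate_curves: Sequence[ODCurve],
    config: GrowthConfig,
    boot: BootstrapConfig,
) -> dict[str, tuple[Optional[float], Optional[tuple[float, float]]]]:
    """Point estimates and BCa intervals across replicate wells.

    The point estimate of each parameter is the mean of the per-well
    estimates; the interval is a BCa bootstrap resampling wells. A
    parameter undefined in more than half the wells yields an undefined
    (None, None) entry.
    """
    if len(replicate_curves) < 2:
        raise ValueError("bootstrap_growth requires at least 2 replicate wells")
    fits = [fit_growth(c, config) for c in replicate_curves]
    out: dict[str, tuple[Optional[float], Optional[tuple[float, float]]]] = {}
    n_wells = len(fits)
    for name in PARAMETERS:
        vals = [f.parameter(name) for f in fits]
        defined = [v for v in vals if v is not None]
        if len(defined) <= n_wells / 2 or len(defined) < 2:
            out[name] = (None, None)
            continue
        est = float(np.mean(defined))
        out[name] = (est, bca_interval(defined, boot))
    return out


def log2_ratio(evolved: GrowthFit, ancestor: GrowthFit) -> dict[str, Optional[float]]:
    """Elementwise log2(evolved / ancestor) of growth parameters.

    Undefined or non-positive components propagate as None.
    """
    out: dict[str, Optional[float]] = {}
    for name in PARAMETERS:
        e, a = evolved.parameter(name), ancestor.parameter(name)
        if e is None or a is None or e <= 0 or a <= 0:
            out[name] = None
        else:
            out[name] = math.log2(e / a)
    return out
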