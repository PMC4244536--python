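"""Pseudo-first-order rate fitting for imidazole C2 H/D exchange.

Uptake (HDX): the two-peak statistic obeys ``ln Y = k t`` with no
intercept (the reference envelope defines t = 0, where Y = 1), so k is the
through-origin least-squares slope of ln Y on t.

Loss (DHX): the deuterated fraction obeys ``d(t) = d0 * exp(-k t)``; k and
d0 come from ordinary least squares of ln d on t with a free intercept,
with d estimated per point by envelope deconvolution against the natural
envelope.

Fits are unweighted in log space.  Points whose statistic is non-positive
under noise are excluded with a warning, never clamped — clamping would
bias the log-space slope.  Points flagged as post-quench holds (exchange
chemically stopped by acidification) are excluded: they carry no
additional exchange information at their wall-clock time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .deuteration import IsotopeEnvelope, compute_Y, estimate_fraction
from .peptide import Peptide, elemental_composition, natural_envelope

__all__ = ["TimePoint", "ExchangeTimeSeries", "RateFit", "fit_hdx_rate", "fit_dhx_rate", "half_life"]

HDX = "HDX"
DHX = "DHX"


@dataclass(frozen=True)
class TimePoint:
    t: float  # hours
    envelope: IsotopeEnvelope
    quenched: bool = False  # acid-quenched hold: no further exchange after quench


@dataclass
class ExchangeTimeSeries:
    """Ordered (time, envelope) observations for one peptide at one pH."""

    peptide: Peptide
    direction: str  # HDX | DHX
    pH: float
    points: List[TimePoint]
    reference: IsotopeEnvelope  # the t = 0 envelope
    temperature: float = 40.0  # deg C, metadata
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in (HDX, DHX):
            raise ValueError(f"direction must be HDX or DHX, got {self.direction!r}")
        times = [p.t for p in self.points]
        if any(t < 0 for t in times):
            raise ValueError("times must be >= 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.points])


@dataclass(frozen=True)
class RateFit:
    """A fitted pseudo-first-order rate constant with diagnostics."""

    k: float  # h^-1
    stderr_k: float
    r_squared: float
    n_points: int
    method: str  # "Y-regression" | "fraction-regression"
    d0: Optional[float] = None  # initial deuterated fraction (DHX only)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("rate constant must be non-negative")


def _usable(series: ExchangeTimeSeries, values: Sequence[float], what: str) -> Tuple[np.ndarray, np.ndarray, int]:
    """Drop post-quench holds and non-positive statistics; return (t, value, n_excluded)."""
    ts, vs, dropped = [], [], 0
    for pt, v in zip(series.points, values):
        if pt.quenched:
            dropped += 1
            continue
        if v is None or v <= 0 or not math.isfinite(v):
            warnings.warn(
                f"excluding t={pt.t} h: non-positive {what} ({v}); "
                "noise can push the statistic below its valid range",
                stacklevel=3,
            )
            dropped += 1
            continue
        ts.append(pt.t)
        vs.append(v)
    return np.array(ts), np.array(vs), dropped


def fit_hdx_rate(series: ExchangeTimeSeries) -> RateFit:
    """Fit k from ln Y = k t (through the origin) for an uptake series."""
    if series.direction != HDX:
        raise ValueError("fit_hdx_rate requires an HDX series")
    ys = []
    for pt in series.points:
        try:
            ys.append(compute_Y(pt.envelope, series.reference))
        except ZeroDivisionError:
            ys.append(None)
    t, y, dropped = _usable(series, ys, "Y")
    if t.size < 3:
        raise ValueError(f"only {t.size} usable points (need >= 3) for an HDX fit")
    lny = np.log(y)
    stt = float(t @ t)
    if stt == 0:
        raise ValueError("all usable timepoints are at t = 0")
    k = float(t @ lny) / stt
    resid = lny - k * t
    dof = max(t.size - 1, 1)
    stderr = math.sqrt(float(resid @ resid) / dof / stt)
    sstot = float(lny @ lny)
    r2 = 1.0 - float(resid @ resid) / sstot if sstot > 0 else 1.0
    return RateFit(k=max(k, 0.0), stderr_k=stderr, r_squared=max(min(r2, 1.0), 0.0),
                   n_points=int(t.size), method="Y-regression", n_excluded=dropped)


def fit_dhx_rate(series: ExchangeTimeSeries, n_peaks: Optional[int] = None) -> RateFit:
    """Fit k and d0 from ln d = ln d0 - k t for a loss series.

    The per-point deuterated fraction is estimated by mixture deconvolution
    against the peptide's theoretical natural envelope.
    """
    if series.direction != DHX:
        raise ValueError("fit_dhx_rate requires a DHX series")
    # observed envelopes span the natural lattice plus one shift offset
    npk = n_peaks or max(2, max(len(p.envelope) for p in series.points) - 1)
    nat = natural_envelope(elemental_composition(series.peptide), npk)
    ds = [estimate_fraction(pt.envelope, nat).d for pt in series.points]
    t, d, dropped = _usable(series, ds, "deuterated fraction d")
    if t.size < 3:
        raise ValueError(f"only {t.size} usable points (need >= 3) for a DHX fit")
    lnd = np.log(d)
    slope, intercept = np.polyfit(t, lnd, 1)
    k = max(-float(slope), 0.0)
    d0 = float(np.exp(intercept))
    resid = lnd - (slope * t + intercept)
    dof = max(t.size - 2, 1)
    sxx = float(np.sum((t - t.mean()) ** 2))
    stderr = math.sqrt(float(resid @ resid) / dof / sxx) if sxx > 0 else math.inf
    sstot = float(np.sum((lnd - lnd.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sstot if sstot > 0 else 1.0
    return RateFit(k=k, stderr_k=stderr, r_squared=max(min(r2, 1.0), 0.0),
                   n_points=int(t.size), method="fraction-regression", d0=d0, n_excluded=dropped)


def half_life(fit) -> float:
    """Exchange half-life ln(2)/k in hours; +inf when k = 0."""
    k = fit.k if isinstance(fit, RateFit) else float(fit)
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    if k == 0:
        return math.inf
    return math.log(2) / k
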