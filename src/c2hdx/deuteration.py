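"""Deuterium quantification from isotope envelopes.

Two estimators of the single-site deuterated fraction *d* of an observed
envelope are provided:

* :func:`compute_Y` — the two-peak ratio statistic
  ``Y = I_{M+1}(t)/I_M(t) - I_{M+1}(0)/I_M(0) + 1``.  For a single
  exchanging site it equals ``1/(1-d)``, so ``ln Y`` grows linearly in
  time with the pseudo-first-order rate constant as slope.  Only the M and
  M+1 peaks enter.
* :func:`estimate_fraction` — least-squares deconvolution of the observed
  envelope as the mixture ``(1-d)*natural + d*shift(natural, +1)`` over
  all available peaks.  Noiseless single-site data give identical answers;
  the mixture estimator is the robust choice for the loss (DHX) direction
  where the M peak of a fully deuterated start is vanishingly small.

Envelopes live on an integer isotope-offset lattice (offset 0 = the
monoisotopic peak).  The ~2.9 mDa difference between a 2H substitution
and a 13C isotopologue is deliberately not resolved: the analysis is
unit-resolution, as is the two-peak statistic it reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "IsotopeEnvelope",
    "DeuterationEstimate",
    "compute_Y",
    "estimate_fraction",
    "count_sites",
    "shift_envelope",
]


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Peak intensities at integer isotope offsets from the monoisotopic peak."""

    intensities: np.ndarray
    charge: int = 1
    base_mz: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("an envelope needs at least 2 isotope peaks")
        if np.any(arr < 0):
            raise ValueError("peak intensities must be non-negative")
        if not np.any(arr > 0):
            raise ValueError("envelope is identically zero")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")

    def normalized(self) -> "IsotopeEnvelope":
        return IsotopeEnvelope(self.intensities / self.intensities.sum(), self.charge, self.base_mz)

    def __len__(self) -> int:
        return self.intensities.size


def _as_array(env) -> np.ndarray:
    if isinstance(env, IsotopeEnvelope):
        return env.intensities
    arr = np.asarray(env, dtype=float)
    if arr.size < 2:
        raise ValueError("an envelope needs at least 2 isotope peaks")
    return arr


def shift_envelope(env: np.ndarray, n: int = 1) -> np.ndarray:
    """Shift an intensity vector up by ``n`` isotope offsets, growing the array."""
    arr = np.asarray(env, dtype=float)
    return np.concatenate([np.zeros(n), arr])


@dataclass(frozen=True)
class DeuterationEstimate:
    """Result of envelope deconvolution for a single exchange site."""

    d: float
    y_value: float
    saturated: bool = False  # d == 1: Y is unbounded, flagged instead of inf
    site_count: Optional[int] = None
    residual: float = field(default=0.0, compare=False)


def compute_Y(env_t, env_0) -> float:
    """Two-peak deuteration statistic from M and M+1 intensities.

    ``Y = I_{M+1}(t)/I_M(t) - I_{M+1}(0)/I_M(0) + 1``; equals 1 when no
    exchange has occurred and ``1/(1-d)`` for single-site occupancy *d*.
    """
    a_t = _as_array(env_t)
    a_0 = _as_array(env_0)
    if a_t[0] <= 0:
        raise ZeroDivisionError("M peak of the time-t envelope is zero: Y is undefined")
    if a_0[0] <= 0:
        raise ZeroDivisionError("M peak of the reference (t=0) envelope is zero: Y is undefined")
    return a_t[1] / a_t[0] - a_0[1] / a_0[0] + 1.0


def estimate_fraction(env_obs, env_natural) -> DeuterationEstimate:
    """Least-squares single-site deuterated fraction of an observed envelope.

    Both envelopes are normalized and zero-padded to a common length; *d*
    minimizes ``|| obs - ((1-d) nat + d shift(nat,+1)) ||^2`` over [0, 1],
    which is a scalar projection clipped to the unit interval.
    """
    obs = _as_array(env_obs).astype(float)
    nat = _as_array(env_natural).astype(float)
    if obs.sum() <= 0 or nat.sum() <= 0:
        raise ValueError("degenerate (all-zero) envelope")
    obs = obs / obs.sum()
    nat = nat / nat.sum()
    n = max(obs.size, nat.size + 1)
    obs = np.pad(obs, (0, n - obs.size))
    nat_p = np.pad(nat, (0, n - nat.size))
    sh = np.pad(shift_envelope(nat, 1), (0, n - nat.size - 1))
    direction = sh - nat_p
    denom = float(direction @ direction)
    d = float(np.clip((obs - nat_p) @ direction / denom, 0.0, 1.0))
    resid = float(np.sum((obs - ((1 - d) * nat_p + d * sh)) ** 2))
    saturated = d >= 1.0
    y = math.inf if saturated else 1.0 / (1.0 - d)
    return DeuterationEstimate(d=d, y_value=y, saturated=saturated, residual=resid)


def count_sites(env_obs, env_natural, max_sites: int = 3, occupancy_threshold: float = 0.05) -> int:
    """Number of exchanged sites resolvable in an observed envelope.

    Fits a non-negative least-squares mixture of the natural envelope
    shifted by 0..max_sites offsets and reports the largest shift whose
    normalized weight reaches ``occupancy_threshold``.  The single-shift
    outcome automates the "exactly one deuteron incorporated" sanity check
    run before a loss-direction experiment.
    """
    if max_sites < 1:
        raise ValueError("max_sites must be >= 1")
    if not 0 < occupancy_threshold < 1:
        raise ValueError("occupancy_threshold must be in (0, 1)")
    obs = _as_array(env_obs).astype(float)
    nat = _as_array(env_natural).astype(float)
    if obs.sum() <= 0 or nat.sum() <= 0:
        raise ValueError("degenerate (all-zero) envelope")
    obs = obs / obs.sum()
    nat = nat / nat.sum()
    n = max(obs.size, nat.size + max_sites)
    obs = np.pad(obs, (0, n - obs.size))
    cols = [np.pad(shift_envelope(nat, s) if s else nat, (0, n - nat.size - s)) for s in range(max_sites + 1)]
    weights, _ = nnls(np.column_stack(cols), obs)
    total = weights.sum()
    if total <= 0:
        return 0
    weights = weights / total
    above = np.flatnonzero(weights >= occupancy_threshold)
    return int(above.max()) if above.size else 0
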