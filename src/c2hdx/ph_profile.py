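"""pH-rate profile of imidazole C2 exchange: sigmoid fitting for pKa and k_max.

The exchange rate depends on the product of imidazolium (protonated ring)
and deuteroxide concentrations, which collapses to the titration form

    k(pH) = k_max / (1 + 10**(pKa - pH))

— a sigmoid rising through acidic pH and plateauing at k_max in the
alkaline limit, with the ring N-H pKa at the inflection.  The equivalent
pointwise rearrangement ``pKa = pH + log10((k_max - k)/k)`` is kept as a
diagnostic; the fit itself runs in the k-domain to avoid blowing up noise
near the plateau where k ~ k_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .kinetics import RateFit

__all__ = ["RateProfile", "ProfileFit", "model_rate", "pointwise_pKa", "fit_profile"]

#: min(k)/max(k) above which the scanned pH window saw no titration rise
#: (every point effectively on the plateau) and pKa is under-determined.
FLATNESS_RATIO = 0.6


def model_rate(pH, pKa: float, k_max: float):
    """Sigmoidal exchange rate k(pH); strictly increasing, bounded by k_max."""
    if k_max <= 0:
        raise ValueError("k_max must be positive")
    return k_max / (1.0 + 10.0 ** (pKa - np.asarray(pH, dtype=float)))


def pointwise_pKa(pH: float, k: float, k_max: float) -> float:
    """Invert the titration curve at a single point: pKa = pH + log10((k_max-k)/k)."""
    if not 0 < k < k_max:
        raise ValueError(f"k must satisfy 0 < k < k_max (got k={k}, k_max={k_max})")
    return pH + math.log10((k_max - k) / k)


@dataclass
class RateProfile:
    """Rate constants of one peptide across a pH series."""

    points: List[Tuple[float, Union[RateFit, float]]]
    direction: str = "HDX"
    peptide: Optional[object] = None

    def __post_init__(self) -> None:
        phs = [p for p, _ in self.points]
        if any(not math.isfinite(p) for p in phs):
            raise ValueError("pH values must be finite")
        if len(set(phs)) < 4:
            raise ValueError("profile fitting needs >= 4 distinct pH values")

    @property
    def pH(self) -> np.ndarray:
        return np.array([p for p, _ in self.points])

    @property
    def k(self) -> np.ndarray:
        return np.array([f.k if isinstance(f, RateFit) else float(f) for _, f in self.points])

    @property
    def stderr(self) -> np.ndarray:
        return np.array([f.stderr_k if isinstance(f, RateFit) else np.nan for _, f in self.points])


@dataclass(frozen=True)
class ProfileFit:
    pKa: float
    k_max: float  # h^-1
    residual_sse: float  # (h^-1)^2
    n_points: int
    warnings: Tuple[str, ...] = field(default=())


def fit_profile(profile: RateProfile, weighted: bool = False) -> ProfileFit:
    """Nonlinear least squares of the titration sigmoid over (pKa, k_max).

    Initialization: k_max at 1.05x the largest observed k, pKa at the pH
    whose k is nearest half of that.  Unweighted by default; ``weighted``
    scales residuals by the per-point rate standard errors when available.
    Degenerate coverage (all points on the plateau, or a fitted pKa far
    outside the scanned window) attaches warnings rather than failing
    silently.
    """
    pH = profile.pH
    k = profile.k
    # k = 0 observations are legitimate data for the k-domain fit (a noisy
    # acidic-limb rate clamped at zero); only negatives are invalid, and the
    # plateau must be nonzero for the sigmoid to be identifiable.
    if np.any(k < 0):
        raise ValueError("rate constants must be non-negative")
    if not np.any(k > 0):
        raise ValueError("all rate constants are zero; nothing to fit")
    k_top = float(k.max())
    k_max0 = 1.05 * k_top
    pKa0 = float(pH[np.argmin(np.abs(k - k_max0 / 2))])

    sigma = None
    if weighted:
        se = profile.stderr
        if np.all(np.isfinite(se)) and np.all(se > 0):
            sigma = se

    def resid(theta):
        r = model_rate(pH, theta[0], theta[1]) - k
        return r / sigma if sigma is not None else r

    sol = least_squares(resid, x0=[pKa0, k_max0], bounds=([-np.inf, 1e-30], [np.inf, np.inf]),
                        xtol=1e-10, ftol=1e-10, gtol=1e-10)
    if not sol.success:
        raise RuntimeError(f"profile fit did not converge: {sol.message}")
    pKa, k_max = float(sol.x[0]), float(sol.x[1])
    sse = float(np.sum((model_rate(pH, pKa, k_max) - k) ** 2))

    warns: List[str] = []
    if float(k.min()) > FLATNESS_RATIO * k_top:
        warns.append(
            "titration-not-sampled: min(k)/max(k) > "
            f"{FLATNESS_RATIO}; every point sits on the plateau and pKa is under-determined"
        )
    if k_top < FLATNESS_RATIO * k_max:
        warns.append("plateau-not-sampled: largest observed k is well below the fitted k_max")
    lo, hi = float(pH.min()) - 2.0, float(pH.max()) + 2.0
    if not lo <= pKa <= hi:
        warns.append(f"pKa {pKa:.2f} outside the scanned pH range [{pH.min():.2f}, {pH.max():.2f}] +/- 2")
    return ProfileFit(pKa=pKa, k_max=k_max, residual_sse=sse, n_points=int(pH.size), warnings=tuple(warns))
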