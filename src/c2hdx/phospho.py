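"""Panel summaries and the phosphohistidine call from exchange-rate suppression.

Phosphorylation of a ring nitrogen places a negative charge next to the C2
carbon and collapses the exchange rate constant by roughly two orders of
magnitude relative to the unmodified histidine, which is the observable
this module turns into a call.

Panel spreads are reported as the *population* standard deviation (divisor
n, not n-1): with seven-peptide panels this is the convention that matches
the printed relative spreads of the reference rate tables shipped as
fixtures, and it is stated here so nobody "fixes" it to the sample SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["PanelSummary", "PhosphoCall", "summarize_panel", "classify_phospho", "orders_of_magnitude"]

PHOSPHORYLATED = "phosphorylated"
UNMODIFIED = "unmodified"
INDETERMINATE = "indeterminate"

#: Width of the indeterminate band below the decision threshold (orders of magnitude).
INDETERMINATE_BAND = 0.25


@dataclass(frozen=True)
class PanelSummary:
    values: tuple
    mean: float
    pop_sd: float
    rel_sd_percent: float
    min: float
    max: float

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PhosphoCall:
    k_observed: float
    k_reference: float
    ratio_orders: float
    call: str
    threshold_orders: float


def summarize_panel(values: Sequence[float]) -> PanelSummary:
    """Mean, population SD, relative SD (%), and range of a rate panel."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("a panel summary needs at least 2 values")
    if np.any(arr <= 0):
        raise ValueError("rate constants must be positive")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=0))
    return PanelSummary(values=tuple(arr), mean=mean, pop_sd=sd,
                        rel_sd_percent=100.0 * sd / mean,
                        min=float(arr.min()), max=float(arr.max()))


def classify_phospho(k_observed: float, k_reference: float, threshold_orders: float = 1.5) -> PhosphoCall:
    """Call phosphorylation from the rate suppression in orders of magnitude.

    ``ratio_orders = log10(k_reference / k_observed)``; at or above the
    threshold the site is called phosphorylated, within ``threshold -
    0.25`` of it the call is indeterminate, below that unmodified.  A zero
    observed rate is a saturated phosphorylated call.
    """
    if k_reference <= 0:
        raise ValueError("k_reference must be positive")
    if k_observed < 0:
        raise ValueError("k_observed must be non-negative")
    if k_observed == 0:
        return PhosphoCall(k_observed, k_reference, math.inf, PHOSPHORYLATED, threshold_orders)
    ratio = math.log10(k_reference / k_observed)
    if ratio >= threshold_orders:
        call = PHOSPHORYLATED
    elif ratio >= threshold_orders - INDETERMINATE_BAND:
        call = INDETERMINATE
    else:
        call = UNMODIFIED
    return PhosphoCall(k_observed, k_reference, ratio, call, threshold_orders)


def orders_of_magnitude(panel_unmod: PanelSummary, panel_phos: PanelSummary) -> float:
    """log10 separation of the mean unmodified and mean phosphorylated rates."""
    if panel_unmod.mean <= 0 or panel_phos.mean <= 0:
        raise ValueError("panel means must be positive")
    return math.log10(panel_unmod.mean / panel_phos.mean)
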