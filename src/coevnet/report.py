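"""Odds-ratio transforms, significance markers and the in-degree curve.

Coefficients of the network choice equation are log odds-ratios: a
coefficient b multiplies the odds of a choice by exp(b), i.e. changes them
by 100*(exp(b) - 1) percent.  Significance uses the two-sided normal
approximation to beta / s.e.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "odds_percent",
    "significance_marker",
    "indegree_activity_curve",
]

#: (two-sided p threshold, marker), most stringent first
_MARKERS = [(0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "†")]


def odds_percent(b: float) -> float:
    """Percent change in choice odds implied by coefficient ``b``.

    100 * (exp(b) - 1), rounded to one decimal.  E.g. b = 0.45 -> 56.8.
    """
    if not np.isfinite(b):
        raise ValueError("coefficient must be finite")
    return round(100.0 * (np.exp(b) - 1.0), 1)


def significance_marker(beta: float, se: float) -> str:
    """Marker string for the two-sided normal test of beta / se.

    ``***`` p<0.001, ``**`` p<0.01, ``*`` p<0.05, ``†`` p<0.1, else "".
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    for threshold, marker in _MARKERS:
        if p < threshold:
            return marker
    return ""


def indegree_activity_curve(
    beta_lin: float, beta_sq: float, max_indegree: int
) -> pd.DataFrame:
    """Per-out-tie objective contribution of the in-degree activity terms.

    Rows d = 0..max_indegree with contribution beta_lin * d + beta_sq * d**2
    — the combined linear and squared in-degree activity effects per
    outgoing tie, showing how receiving support changes the propensity to
    provide it (the "source vs sink" curve).  Contributions of other
    effects are deliberately excluded.
    """
    if max_indegree < 1:
        raise ValueError("max_indegree must be >= 1")
    d = np.arange(max_indegree + 1)
    return pd.DataFrame(
        {"indegree": d, "objective_contribution": beta_lin * d + beta_sq * d**2}
    )
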