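"""Goodness-of-fit statistics for simulated vs observed series.

Implements the crop-modelling standards: Willmott's index of agreement (d),
Nash-Sutcliffe modelling efficiency (ME), root-mean-square error and signed
mean bias.  The d-index uses the Willmott (1981) convention: primed terms
are deviations from the *observed* mean,

    d = 1 - sum (m_i - S_i)^2 / sum (|S_i - mbar| + |m_i - mbar|)^2 ,

giving d in [0, 1] with 1 for perfect agreement.  ME = 1 - sum(m-S)^2 /
sum(m - mbar)^2 ranges over (-inf, 1]; ME = 0 means the model predicts no
better than the observed mean.  Bias is simulated minus observed (positive
= over-prediction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PairedSeries", "DegenerateSeriesError", "d_index",
           "model_efficiency", "rmse", "bias", "evaluate_report"]


class DegenerateSeriesError(ValueError):
    """The statistic's denominator vanishes for this series."""


@dataclass(frozen=True)
class PairedSeries:
    """Aligned observed/simulated values with pairwise deletion of missing."""

    observed: np.ndarray
    simulated: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.observed, dtype=float)
        s = np.asarray(self.simulated, dtype=float)
        if m.shape != s.shape or m.ndim != 1:
            raise ValueError("observed and simulated must be 1-D of equal length")
        keep = ~(np.isnan(m) | np.isnan(s))
        m, s = m[keep], s[keep]
        if len(m) < 2:
            raise ValueError("need at least 2 complete pairs")
        object.__setattr__(self, "observed", m)
        object.__setattr__(self, "simulated", s)

    @property
    def n(self) -> int:
        return len(self.observed)


def d_index(p: PairedSeries) -> float:
    """Willmott index of agreement, in [0, 1]."""
    m, s = p.observed, p.simulated
    mbar = m.mean()
    num = float(((m - s) ** 2).sum())
    den = float(((np.abs(s - mbar) + np.abs(m - mbar)) ** 2).sum())
    if den == 0.0:
        raise DegenerateSeriesError(
            "d-index undefined: both series are constant at the observed mean")
    return 1.0 - num / den


def model_efficiency(p: PairedSeries) -> float:
    """Nash-Sutcliffe modelling efficiency, in (-inf, 1]."""
    m, s = p.observed, p.simulated
    den = float(((m - m.mean()) ** 2).sum())
    if den == 0.0:
        raise DegenerateSeriesError("ME undefined: observed series is constant")
    return 1.0 - float(((m - s) ** 2).sum()) / den


def rmse(p: PairedSeries) -> float:
    """Root-mean-square error, in the units of the series."""
    m, s = p.observed, p.simulated
    return math.sqrt(float(((m - s) ** 2).mean()))


def bias(p: PairedSeries) -> float:
    """Signed mean error, simulated minus observed (positive = over-prediction)."""
    return float((p.simulated - p.observed).mean())


def evaluate_report(p: PairedSeries) -> dict:
    """Bundle all statistics into a JSON-friendly report."""
    mbar = float(p.observed.mean())
    r = rmse(p)
    return {
        "n": p.n,
        "units": p.units,
        "observed_mean": mbar,
        "bias": bias(p),
        "rmse": r,
        "rmse_pct_of_mean": (100.0 * r / mbar) if mbar != 0 else float("nan"),
        "d": d_index(p),
        "me": model_efficiency(p),
    }
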