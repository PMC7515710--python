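"""Small quantitative assay computations: decay half-lives and qPCR folds.

Half-life fitting supports two conventions.  ``linear`` regresses percent
remaining directly on time and reads off the time at which the fitted line
crosses 50% — the classic graphical estimate for a decay curve.
``log_linear`` regresses ln(percent) on time, assuming first-order
(exponential) decay, and returns t1/2 = -ln2 / slope.  Both refuse to report
a half-life for non-decaying series (slope >= 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class DecayFit:
    method: str            # "linear" or "log_linear"
    slope: float
    intercept: float
    t_half: float | None   # minutes; None when no decay
    r_squared: float
    n_points: int
    n_excluded_zero: int = 0   # zero/negative percents dropped by log_linear
    reason: str | None = None  # set when t_half is None


@dataclass
class QpcrEnrichment:
    delta_ct_experimental: float
    delta_ct_mock: float
    delta_delta_ct: float
    fold: float


def fit_half_life(times: Sequence[float], percents: Sequence[float],
                  method: str = "linear") -> DecayFit:
    """Fit a decay time-course (minutes, percent remaining) and return the
    half-life.

    ``linear``: least-squares of percent vs time; t1/2 = (50 - intercept)/slope.
    ``log_linear``: least-squares of ln(percent) vs time (non-positive
    percents excluded, counted); t1/2 = -ln2/slope.
    Slope >= 0 or a non-positive t1/2 yields t_half=None with a reason.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(percents, dtype=float)
    if t.size != y.size:
        raise ValueError("times and percents differ in length")
    if (y < 0).any():
        raise ValueError("percents must be >= 0")
    n_excluded = 0
    if method == "log_linear":
        keep = y > 0
        n_excluded = int((~keep).sum())
        t, y = t[keep], np.log(y[keep])
    elif method != "linear":
        raise ValueError(f"unknown method {method!r}")
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need >= 2 distinct time points")
    res = stats.linregress(t, y)
    fit = DecayFit(method, float(res.slope), float(res.intercept), None,
                   float(res.rvalue ** 2), int(t.size), n_excluded)
    if res.slope >= 0:
        fit.reason = "non-decaying"
        return fit
    if method == "linear":
        t_half = (50.0 - res.intercept) / res.slope
    else:
        t_half = -math.log(2.0) / res.slope
    if t_half <= 0:
        fit.reason = "non-positive half-life"
        return fit
    fit.t_half = float(t_half)
    return fit


def bulk_half_life(times: Sequence[float], total_counts: Sequence[float],
                   stable_counts: float, method: str = "linear") -> DecayFit:
    """Bulk mRNA half-life from total isotope counts with a stable-RNA
    baseline.

    The stable count (taken long after transcription arrest) is subtracted
    from each total; the t=0 remainder defines 100% mRNA and the percent
    series is fit with :func:`fit_half_life`.
    """
    t = np.asarray(times, dtype=float)
    total = np.asarray(total_counts, dtype=float)
    if t.size != total.size:
        raise ValueError("times and counts differ in length")
    mrna = total - stable_counts
    order = np.argsort(t)
    if mrna[order][0] <= 0:
        raise ValueError("no labile signal: counts at t=0 do not exceed "
                         "the stable-RNA baseline")
    percents = 100.0 * mrna / mrna[order][0]
    return fit_half_life(t, np.clip(percents, 0.0, None), method=method)


def chip_qpcr_enrichment(ct_sample: float, adjusted_ct_input_sample: float,
                         ct_mock: float, adjusted_ct_input_mock: float
                         ) -> QpcrEnrichment:
    """ChIP-qPCR enrichment fold via the double-delta-Ct method:
    dCt = Ct(sample) - adjusted Ct(input) per arm, ddCt = dCt(experimental)
    - dCt(mock), fold = 2^(-ddCt)."""
    d_exp = ct_sample - adjusted_ct_input_sample
    d_mock = ct_mock - adjusted_ct_input_mock
    ddct = d_exp - d_mock
    return QpcrEnrichment(d_exp, d_mock, ddct, 2.0 ** (-ddct))


def adjust_input_ct(ct_input: float, dilution_factor: float) -> float:
    """Dilution-adjust an input Ct: Ct - log2(dilution_factor)."""
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    return ct_input - math.log2(dilution_factor)
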