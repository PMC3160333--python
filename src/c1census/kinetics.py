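"""Radiotracer time-course analysis: oxidation/incorporation rates and fate.

Cumulative radiotracer curves (label recovered as CO2, label recovered in
TCA-insoluble biomass) start out linear while substrate and cell activity
are unperturbed, then saturate.  Rates are estimated by ordinary least
squares over the *initial linear part* of each curve, formalised here as
the longest prefix of timepoints, anchored at the first sample, whose
linear fit reaches ``r^2 >= r2_min``.  Rates are normalised per 10^10
cells, the conventional unit for dilute marine cultures.

The fate of a substrate is summarised by the fraction of utilisation that
is incorporated into biomass, ``v_inc / (v_inc + v_ox)``, reported as a
percent; C1 substrates in SAR11-dominated systems sit near a few percent
(energy without biomass — methylovory) while sugars sit near 30%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

LIVE = "live"
KILLED = "killed"


@dataclass(frozen=True)
class TimeCourse:
    """Cumulative tracer measurements for one vial."""

    times: np.ndarray          # hours, strictly increasing
    oxidized: np.ndarray       # nmol label recovered as CO2 (cumulative)
    incorporated: np.ndarray   # nmol label in biomass (cumulative)
    treatment: str             # LIVE or KILLED
    cells_total: float         # cells in the vial
    substrate_conc: float = 0.0  # molar, bookkeeping only

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 3:
            raise ValueError("need at least 3 timepoints")
        if np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ValueError("times must be non-negative and strictly increasing")
        for name in ("oxidized", "incorporated"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != t.shape or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite and match times in length")
        if self.treatment not in (LIVE, KILLED):
            raise ValueError(f"unknown treatment {self.treatment!r}")

    def channel(self, name: str) -> np.ndarray:
        if name not in ("oxidized", "incorporated"):
            raise ValueError(f"unknown channel {name!r}")
        return np.asarray(getattr(self, name), dtype=float)


@dataclass(frozen=True)
class RateEstimate:
    """Least-squares rate over the initial linear window of a curve."""

    rate: float                # nmol per 10^10 cells per hour
    intercept: float           # nmol (vial scale)
    n_points_used: int
    r_squared: float
    linear_window: tuple[int, int]  # (first, last) timepoint indices, inclusive
    flagged: bool = False      # True when no prefix met r2_min


def _prefix_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r^2 of the OLS line through (t, y).

    A perfectly flat or perfectly fitted prefix (zero residual) counts as
    r^2 = 1 so that noiseless data always qualifies.
    """
    tc, yc = t - t.mean(), y - y.mean()
    slope = float(np.dot(tc, yc) / np.dot(tc, tc))
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0 or ss_res <= 1e-30 * max(ss_tot, 1.0):
        r2 = 1.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), r2


def initial_linear_rate(tc: TimeCourse, channel: str = "oxidized",
                        r2_min: float = 0.95) -> RateEstimate:
    """Fit the initial linear phase and scale the slope per 10^10 cells.

    The window is the longest prefix (>= 3 points, starting at the first
    timepoint) whose fit reaches ``r2_min``; if none qualifies the first
    three points are used and the estimate is flagged.
    """
    y = tc.channel(channel)
    t = np.asarray(tc.times, dtype=float)
    best = None
    for k in range(3, len(t) + 1):
        slope, intercept, r2 = _prefix_fit(t[:k], y[:k])
        if r2 >= r2_min:
            best = (k, slope, intercept, r2)
    if best is None:
        k = 3
        slope, intercept, r2 = _prefix_fit(t[:k], y[:k])
        flagged = True
    else:
        k, slope, intercept, r2 = best
        flagged = False
    if tc.cells_total <= 0:
        raise ValueError("cells_total must be positive to normalise the rate")
    per_1e10 = slope * (1e10 / tc.cells_total)
    return RateEstimate(rate=per_1e10, intercept=intercept, n_points_used=k,
                        r_squared=r2, linear_window=(0, k - 1), flagged=flagged)


def killed_correction(live: RateEstimate, killed: RateEstimate) -> float:
    """Subtract the formalin-killed (abiotic) background rate, clamped at 0."""
    diff = live.rate - killed.rate
    if diff < 0:
        warnings.warn(
            f"killed control rate ({killed.rate:.4g}) exceeds live rate "
            f"({live.rate:.4g}); corrected rate clamped to 0", stacklevel=2)
        return 0.0
    return diff


def fate_partition(ox_rate: float, inc_rate: float) -> float | None:
    """Percent of substrate utilisation incorporated: 100 * inc/(inc+ox)."""
    if ox_rate < 0 or inc_rate < 0:
        raise ValueError("rates must be non-negative")
    total = ox_rate + inc_rate
    if total == 0:
        warnings.warn("both rates are zero; substrate fate undefined", stacklevel=2)
        return None
    return 100.0 * inc_rate / total


def analyze_pair(live: TimeCourse, killed: TimeCourse,
                 r2_min: float = 0.95) -> dict:
    """Full per-substrate analysis: both channels, killed-corrected, fate."""
    out: dict = {}
    for channel in ("oxidized", "incorporated"):
        est_live = initial_linear_rate(live, channel, r2_min)
        est_killed = initial_linear_rate(killed, channel, r2_min)
        out[channel] = {
            "live": est_live,
            "killed": est_killed,
            "corrected_rate": killed_correction(est_live, est_killed),
        }
    out["fraction_incorporated_percent"] = fate_partition(
        out["oxidized"]["corrected_rate"], out["incorporated"]["corrected_rate"])
    return out
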