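"""Non-compartmental analysis of concentration–time profiles.

Implements the standard NCA metric set for an intravenous profile:
C_max and t_max straight from the observed points, AUC by the linear
trapezoidal rule, the terminal elimination rate constant λz by best-fit
log-linear regression, and the derived quantities

    AUC_0–∞  = AUC_0–last + C_last / λz
    AUMC_0–∞ = AUMC_0–last + C_last * t_last / λz + C_last / λz²
    CL       = dose / AUC_0–∞
    MRT      = AUMC_0–∞ / AUC_0–∞
    V_d,ss   = CL * MRT
    T_1/2    = ln 2 / λz

λz uses the conventional best-fit rule: among the last k = 3..n positive
concentrations, pick the log-linear regression maximizing adjusted R²; a
non-decaying terminal phase (an accumulating organ) yields no acceptable
fit and every λz-dependent metric is reported as unavailable (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcentrationProfile",
    "NCAResult",
    "TerminalSlope",
    "auc_linear_trapezoid",
    "terminal_slope",
    "nca_summary",
]


@dataclass(frozen=True)
class ConcentrationProfile:
    """A single compartment's concentration–time profile (µg/mL vs h)."""

    times: np.ndarray
    concentrations: np.ndarray
    dose: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.shape != c.shape or len(t) < 2:
            raise ValueError("times and concentrations must be equal-length vectors (n >= 2)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if self.dose <= 0:
            raise ValueError("dose must be strictly positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class TerminalSlope:
    """Terminal log-linear regression: λz and its diagnostics."""

    lambda_z: float
    n_points: int
    r_squared: float
    adj_r_squared: float
    intercept: float

    @property
    def available(self) -> bool:
        return np.isfinite(self.lambda_z) and self.lambda_z > 0


_UNAVAILABLE = TerminalSlope(np.nan, 0, np.nan, np.nan, np.nan)


def auc_linear_trapezoid(
    profile: ConcentrationProfile,
    t_end: float | None = None,
    t_start: float = 0.0,
) -> float:
    """Linear trapezoidal AUC over ``[t_start, t_end]``.

    When the interval starts before the first observation the first
    observation is the left boundary (no back-extrapolation).  ``t_end``
    defaults to the last observation and must not exceed it; interior
    boundaries are linearly interpolated, so the integral is additive over
    adjacent intervals.
    """
    t, c = profile.times, profile.concentrations
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] + 1e-12:
        raise ValueError(f"t_end={t_end} is beyond the last observation ({t[-1]})")
    t_start = max(t_start, float(t[0]))
    if t_end <= t_start:
        return 0.0
    mask = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[mask], [t_end]))
    cc = np.interp(tt, t, c)
    return float(np.trapezoid(cc, tt))


def _aumc_linear_trapezoid(profile: ConcentrationProfile) -> float:
    t, c = profile.times, profile.concentrations
    return float(np.trapezoid(t * c, t))


def terminal_slope(profile: ConcentrationProfile, min_points: int = 3) -> TerminalSlope:
    """Best-fit λz: log-linear regression over the last k points.

    Scans k from ``min_points`` up to all positive terminal points and
    keeps the regression with the highest adjusted R² among those with a
    negative slope.  Returns an unavailable result (λz = NaN) when no
    decaying terminal stretch exists.
    """
    t, c = profile.times, profile.concentrations
    positive = c > 0
    # use the trailing run of strictly positive concentrations
    idx = np.nonzero(~positive)[0]
    start = idx[-1] + 1 if len(idx) else 0
    t_pos, c_pos = t[start:], c[start:]
    if len(t_pos) < min_points:
        return _UNAVAILABLE
    log_c = np.log(c_pos)
    best = _UNAVAILABLE
    for k in range(min_points, len(t_pos) + 1):
        tt, yy = t_pos[-k:], log_c[-k:]
        if np.ptp(tt) == 0:
            continue
        slope, intercept, r_value, _, _ = stats.linregress(tt, yy)
        if slope >= 0:
            continue
        r2 = r_value**2
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        if not best.available or adj > best.adj_r_squared:
            best = TerminalSlope(-slope, k, r2, adj, intercept)
    return best


@dataclass(frozen=True)
class NCAResult:
    """The NCA metric set for one profile (NaN = unavailable)."""

    label: str
    c_max: float
    t_max: float
    auc_0_last: float
    auc_0_inf: float
    aumc_0_inf: float
    lambda_z: float
    cl: float
    vd_ss: float
    mrt: float
    t_half: float
    extrapolated_fraction: float
    dose: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "c_max": self.c_max,
                "t_max": self.t_max,
                "auc_0_last": self.auc_0_last,
                "auc_0_inf": self.auc_0_inf,
                "aumc_0_inf": self.aumc_0_inf,
                "lambda_z": self.lambda_z,
                "cl": self.cl,
                "vd_ss": self.vd_ss,
                "mrt": self.mrt,
                "t_half": self.t_half,
                "extrapolated_fraction": self.extrapolated_fraction,
            },
            name=self.label,
        )


def nca_summary(profile: ConcentrationProfile) -> NCAResult:
    """Full non-compartmental summary of one concentration profile.

    C_max ties break to the earliest time.  λz-dependent metrics propagate
    as NaN when the terminal phase does not decay (accumulation).
    """
    t, c = profile.times, profile.concentrations
    i_max = int(np.argmax(c))  # argmax returns the first maximum
    c_max, t_max = float(c[i_max]), float(t[i_max])
    auc_last = auc_linear_trapezoid(profile)
    slope = terminal_slope(profile)
    if slope.available:
        lz = slope.lambda_z
        c_last, t_last = float(c[-1]), float(t[-1])
        auc_inf = auc_last + c_last / lz
        aumc_inf = _aumc_linear_trapezoid(profile) + c_last * t_last / lz + c_last / lz**2
        cl = profile.dose / auc_inf
        mrt = aumc_inf / auc_inf
        vd_ss = cl * mrt
        t_half = log(2.0) / lz
        extrap = (auc_inf - auc_last) / auc_inf
    else:
        lz = auc_inf = aumc_inf = cl = mrt = vd_ss = t_half = extrap = float("nan")
    return NCAResult(
        label=profile.label,
        c_max=c_max,
        t_max=t_max,
        auc_0_last=auc_last,
        auc_0_inf=auc_inf,
        aumc_0_inf=aumc_inf,
        lambda_z=lz,
        cl=cl,
        vd_ss=vd_ss,
        mrt=mrt,
        t_half=t_half,
        extrapolated_fraction=extrap,
        dose=profile.dose,
    )
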