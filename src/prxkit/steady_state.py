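"""Coupled NADPH-linked steady-state peroxidase assay analysis.

In the coupled assay (NADPH + thioredoxin reductase + Trx1 + H2O2 +
nanomolar peroxiredoxin) peroxidase turnover is read out as NADPH
consumption at 340 nm (epsilon = 6.22 mM^-1 cm^-1).  A baseline is recorded
before the reaction is started; initial activities are corrected by
subtracting the final baseline slope.  Substrate series are analyzed by a
nonlinear Michaelis-Menten fit, with the three classical linearizations
(Lineweaver-Burk, Eadie-Hofstee, Hanes) computed as outlier diagnostics
only — they are never the reported estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .errors import AssayRangeWarning, InsufficientDataError, InvalidParameterError

#: NADPH molar extinction coefficient at 340 nm
EPSILON_NADPH_mM = 6.22  # mM^-1 cm^-1

#: working band of the assay, Delta A340 per minute
ABS_SLOPE_BAND = (0.02, 0.2)


@dataclass
class SteadyStateAssay:
    """One A340 progress curve plus the windows and constants to reduce it."""

    time: np.ndarray  # s
    a340: np.ndarray
    enzyme_conc: float  # M
    baseline_window: tuple[float, float]  # s
    rate_window: tuple[float, float]  # s
    epsilon_mM: float = EPSILON_NADPH_mM  # mM^-1 cm^-1
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.a340 = np.asarray(self.a340, float)
        if self.time.size != self.a340.size or self.time.size < 4:
            raise InvalidParameterError("time and a340 must have equal length >= 4")
        b0, b1 = self.baseline_window
        r0, r1 = self.rate_window
        if not (b0 < b1 <= r0 < r1):
            raise InvalidParameterError(
                "baseline window must precede and not overlap the rate window"
            )


@dataclass
class InitialRate:
    v: float  # M s^-1, NADPH consumption positive
    v_over_E: float  # s^-1
    baseline_slope: float  # A340 s^-1
    reaction_slope: float  # A340 s^-1
    in_range: bool


@dataclass
class MichaelisFit:
    kcat_app: float  # s^-1
    Km_app: float  # M
    kcat_over_Km: float  # M^-1 s^-1
    Vmax: float  # M s^-1
    linearizations: dict = field(default_factory=dict)
    outlier_flags: np.ndarray | None = None


def _window_slope(t: np.ndarray, y: np.ndarray, window: tuple[float, float]) -> float:
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 2:
        raise InvalidParameterError(f"window {window} covers fewer than 2 points")
    return float(linregress(t[mask], y[mask]).slope)


def initial_rate(assay: SteadyStateAssay) -> InitialRate:
    """Baseline-corrected initial rate of NADPH consumption.

    ``v = (baseline slope - reaction slope) / (epsilon * path)`` in M/s, so
    a falling A340 gives a positive rate.  Slopes outside the assay's
    0.02-0.2 Delta A340/min working band trigger a quality warning.
    """
    b = _window_slope(assay.time, assay.a340, assay.baseline_window)
    r = _window_slope(assay.time, assay.a340, assay.rate_window)
    eps_M = assay.epsilon_mM * 1e3  # M^-1 cm^-1
    v = (b - r) / (eps_M * assay.path_cm)
    abs_per_min = abs(r - b) * 60.0
    in_range = ABS_SLOPE_BAND[0] <= abs_per_min <= ABS_SLOPE_BAND[1]
    if not in_range:
        warnings.warn(
            f"corrected slope {abs_per_min:.3g} Delta A340/min outside the "
            f"{ABS_SLOPE_BAND} working band",
            AssayRangeWarning,
            stacklevel=2,
        )
    v_over_E = v / assay.enzyme_conc if assay.enzyme_conc > 0 else np.nan
    return InitialRate(
        v=v, v_over_E=v_over_E, baseline_slope=b, reaction_slope=r, in_range=in_range
    )


def michaelis_fit(points, enzyme_conc: float) -> MichaelisFit:
    """Nonlinear Michaelis-Menten fit of (substrate, initial-rate) pairs.

    ``points``: iterable of ``([S] in M, v in M/s)``.  Requires >= 4 distinct
    substrate concentrations spanning >= 4-fold.  The reported estimate is
    the nonlinear fit; Lineweaver-Burk, Eadie-Hofstee and Hanes estimates
    are attached as diagnostics, and points with studentized residuals > 3
    are flagged (never removed).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidParameterError("points must be (substrate, rate) pairs")
    S, v = pts[:, 0], pts[:, 1]
    if np.any(S <= 0):
        raise InvalidParameterError("substrate concentrations must be > 0")
    if enzyme_conc <= 0:
        raise InvalidParameterError("enzyme concentration must be > 0")
    uniq = np.unique(S)
    if uniq.size < 4:
        raise InsufficientDataError("need >= 4 distinct substrate concentrations")
    if uniq.max() / uniq.min() < 4.0:
        raise InsufficientDataError("substrate range must span >= 4-fold")

    def resid(params):
        Vmax, Km = params
        return Vmax * S / (Km + S) - v

    sol = least_squares(
        resid, x0=(float(v.max()), float(np.median(S))), method="lm", max_nfev=5000
    )
    Vmax, Km = float(sol.x[0]), float(sol.x[1])
    if Vmax <= 0 or Km <= 0:
        raise InvalidParameterError("fit returned nonpositive Vmax or Km")

    # robust (median-based) residual scale so a single gross outlier does
    # not mask itself by inflating the classical variance estimate
    r = sol.fun
    scale = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    flags = np.abs(r) > 3.0 * scale if scale > 0 else np.zeros(S.size, bool)

    lin: dict[str, dict[str, float]] = {}
    lb = linregress(1.0 / S, 1.0 / v)  # 1/v = Km/Vmax * 1/S + 1/Vmax
    lin["lineweaver_burk"] = {"Vmax": 1.0 / lb.intercept, "Km": lb.slope / lb.intercept}
    eh = linregress(v / S, v)  # v = Vmax - Km * v/S
    lin["eadie_hofstee"] = {"Vmax": eh.intercept, "Km": -eh.slope}
    hn = linregress(S, S / v)  # S/v = S/Vmax + Km/Vmax
    lin["hanes"] = {"Vmax": 1.0 / hn.slope, "Km": hn.intercept / hn.slope}

    return MichaelisFit(
        kcat_app=Vmax / enzyme_conc,
        Km_app=Km,
        kcat_over_Km=(Vmax / enzyme_conc) / Km,
        Vmax=Vmax,
        linearizations=lin,
        outlier_flags=flags,
    )
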