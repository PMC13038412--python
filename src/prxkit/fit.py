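"""Rate-constant inference from stopped-flow traces.

Mirrors the standard stopped-flow workflow: each trace is fit with a sum of
exponentials, ``signal(t) = offset + sum_i a_i exp(-k_obs,i t)``, to obtain
per-phase observed rates; the concentration dependence of each ``k_obs``
(secondary plot) then yields mechanistic constants — a linear dependence
gives the second-order rate constant as its slope (with a possible non-zero
intercept from a reverse reaction), a hyperbolic one gives a plateau and
half-saturation.  Superposition fits hold a subset of the rates fixed at
externally measured values and solve only for amplitudes (plus optional free
phases), as used for hetero-oligomer traces.

Exponential fits use variable projection: for any trial rate vector the
amplitudes and offset are the exact linear least-squares solution, and only
the (log) rates are optimized iteratively, from multiple log-spaced starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .errors import (
    CollinearityError,
    DegenerateDesignError,
    FitFailureError,
    IdentifiabilityWarning,
    InsufficientDataError,
    InvalidParameterError,
)
from .scheme import FluorescenceTrace


@dataclass
class MultistartConfig:
    """Multistart strategy for the nonlinear rate search.

    Rate seeds are drawn (seeded, reproducible) from a log-spaced grid
    between ``1/(10 t_max)`` and ``10/t_min``; the best residual wins, ties
    broken by the smaller parameter norm.
    """

    n_starts: int = 20
    grid_size: int = 40
    seed: int = 0
    max_nfev: int = 2000


@dataclass
class ExponentialFit:
    n_phases: int
    amplitudes: np.ndarray  # aligned with k_obs
    k_obs: np.ndarray  # s^-1, sorted descending
    offset: float
    residual_norm: float
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def model(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return self.offset + sum(
            a * np.exp(-k * t) for a, k in zip(self.amplitudes, self.k_obs)
        )


@dataclass
class SecondaryFit:
    model: str  # "linear" | "hyperbolic"
    x: np.ndarray
    y: np.ndarray
    slope: float | None = None  # M^-1 s^-1
    intercept: float | None = None  # s^-1
    slope_stderr: float | None = None
    intercept_stderr: float | None = None
    plateau: float | None = None  # s^-1
    half_saturation: float | None = None  # M
    aic: dict = field(default_factory=dict)


def _design(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(t)] + [np.exp(-k * t) for k in rates]
    return np.column_stack(cols)


def _varpro_residual(t: np.ndarray, y: np.ndarray, rates: np.ndarray):
    """Best-fit amplitudes+offset for fixed rates, and the residual vector."""
    A = _design(t, rates)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef, A @ coef - y


def fit_exponentials(
    trace: FluorescenceTrace,
    n_phases: int,
    strategy: MultistartConfig | None = None,
) -> ExponentialFit:
    """Multi-exponential least-squares fit of one trace.

    Returns per-phase amplitudes and observed rates (sorted descending) plus
    a constant offset.  Emits an :class:`IdentifiabilityWarning` when any two
    fitted rates are within threefold of each other — for such pairs the
    individual amplitudes are poorly determined.
    """
    if not 1 <= n_phases <= 4:
        raise InvalidParameterError(f"n_phases must be in 1..4, got {n_phases}")
    t, y = trace.time, trace.signal
    if t.size < 4 * n_phases + 2:
        raise InsufficientDataError(
            f"trace has {t.size} points; need >= {4 * n_phases + 2} for {n_phases} phases"
        )
    strategy = strategy or MultistartConfig()

    t_max = t[-1]
    t_min = t[t > 0].min() if np.any(t > 0) else t[1]
    lo, hi = 1.0 / (10.0 * t_max), 10.0 / t_min
    grid = np.geomspace(lo, hi, strategy.grid_size)
    rng = np.random.default_rng(strategy.seed)

    def residual_logk(logk: np.ndarray) -> np.ndarray:
        _, r = _varpro_residual(t, y, np.exp(np.clip(logk, -60.0, 60.0)))
        return r

    best = None  # (residual_norm, param_norm, logk, coef)
    starts = []
    # start 0: evenly spread over the grid; remaining: seeded random subsets
    starts.append(np.log(grid[np.linspace(0, grid.size - 1, n_phases).astype(int)]))
    for _ in range(strategy.n_starts - 1):
        idx = np.sort(rng.choice(grid.size, size=n_phases, replace=False))
        starts.append(np.log(grid[idx]))

    for x0 in starts:
        try:
            sol = least_squares(
                residual_logk, x0, method="lm", max_nfev=strategy.max_nfev
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        sol.x = np.clip(sol.x, -60.0, 60.0)
        rn = float(np.linalg.norm(sol.fun))
        pn = float(np.linalg.norm(sol.x))
        if best is None or (rn, pn) < (best[0], best[1]):
            coef, _ = _varpro_residual(t, y, np.exp(sol.x))
            best = (rn, pn, sol.x, coef)

    if best is None:
        raise FitFailureError(
            f"no multistart converged ({strategy.n_starts} starts, {n_phases} phases)"
        )

    rn, _, logk, coef = best
    rates = np.exp(logk)
    order = np.argsort(rates)[::-1]
    rates = rates[order]
    amps = coef[1:][order]
    offset = float(coef[0])

    warns: list[str] = []
    for i in range(n_phases - 1):
        if rates[i] < 3.0 * rates[i + 1]:
            msg = (
                f"k_obs {rates[i]:.4g} and {rates[i + 1]:.4g} s^-1 are within "
                "threefold; phases weakly identifiable"
            )
            warns.append(msg)
            warnings.warn(msg, IdentifiabilityWarning, stacklevel=2)

    return ExponentialFit(
        n_phases=n_phases,
        amplitudes=amps,
        k_obs=rates,
        offset=offset,
        residual_norm=rn,
        converged=True,
        warnings=warns,
    )


def _aic(rss: float, n: int, k_params: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k_params


def secondary_fit(points, model: str = "linear") -> SecondaryFit:
    """Fit the concentration dependence of one phase's observed rates.

    ``points`` is an iterable of ``(concentration_M, k_obs_s^-1)`` pairs.
    The linear model returns slope (second-order rate constant) and
    intercept with standard errors; the hyperbolic model
    ``k_obs = plateau * x / (K + x)`` returns the plateau and
    half-saturation.  Both models' AIC values are reported so the caller's
    choice can be sanity-checked.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidParameterError("points must be (concentration, k_obs) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x < 0):
        raise InvalidParameterError("concentrations must be >= 0")
    if np.unique(x).size < 3:
        raise InsufficientDataError("need >= 3 distinct concentrations")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("zero variance in concentrations")
    if model not in ("linear", "hyperbolic"):
        raise InvalidParameterError(f"model must be linear or hyperbolic, got {model!r}")

    lin = linregress(x, y)
    rss_lin = float(np.sum((lin.intercept + lin.slope * x - y) ** 2))

    def hyp(params):
        plateau, K = params
        return plateau * x / (K + x) - y

    x0 = (float(y.max()), float(np.median(x)) or float(x.max()) or 1.0)
    sol = least_squares(hyp, x0, method="lm", max_nfev=5000)
    plateau, K = sol.x
    rss_hyp = float(np.sum(sol.fun**2))

    aic = {
        "linear": _aic(rss_lin, x.size, 3),
        "hyperbolic": _aic(rss_hyp, x.size, 3),
    }
    out = SecondaryFit(model=model, x=x, y=y, aic=aic)
    if model == "linear":
        out.slope = float(lin.slope)
        out.intercept = float(lin.intercept)
        out.slope_stderr = float(lin.stderr)
        out.intercept_stderr = float(lin.intercept_stderr)
    else:
        out.plateau = float(plateau)
        out.half_saturation = float(K)
    return out


def superposition_fit(
    trace: FluorescenceTrace,
    preset_kobs,
    n_free: int = 0,
    strategy: MultistartConfig | None = None,
) -> ExponentialFit:
    """Exponential fit with a subset of rates held fixed at preset values.

    Amplitudes of the preset phases (and the offset) are the exact linear
    least-squares solution; any additional free phases are optimized as in
    :func:`fit_exponentials` with the preset columns kept in the design.
    """
    preset = np.asarray(list(preset_kobs), dtype=float)
    if preset.size == 0 or np.any(preset <= 0):
        raise InvalidParameterError("preset rates must be positive")
    for i in range(preset.size):
        for j in range(i + 1, preset.size):
            if abs(preset[i] - preset[j]) <= 1e-6 * max(preset[i], preset[j]):
                raise CollinearityError(
                    f"preset rates {preset[i]} and {preset[j]} are indistinguishable"
                )
    n_total = preset.size + n_free
    if not 1 <= n_total <= 6:
        raise InvalidParameterError("total phase count must be in 1..6")
    t, y = trace.time, trace.signal

    if n_free == 0:
        coef, resid = _varpro_residual(t, y, preset)
        rates, amps, offset = preset, coef[1:], float(coef[0])
        rn = float(np.linalg.norm(resid))
    else:
        strategy = strategy or MultistartConfig()
        t_max = t[-1]
        t_min = t[t > 0].min() if np.any(t > 0) else t[1]
        grid = np.geomspace(1.0 / (10.0 * t_max), 10.0 / t_min, strategy.grid_size)
        rng = np.random.default_rng(strategy.seed)

        def residual_logk(logk):
            free = np.exp(np.clip(logk, -60.0, 60.0))
            _, r = _varpro_residual(t, y, np.concatenate([preset, free]))
            return r

        best = None
        starts = [np.log(grid[np.linspace(0, grid.size - 1, n_free).astype(int)])]
        for _ in range(strategy.n_starts - 1):
            idx = np.sort(rng.choice(grid.size, size=n_free, replace=False))
            starts.append(np.log(grid[idx]))
        for x0 in starts:
            try:
                sol = least_squares(residual_logk, x0, method="lm", max_nfev=strategy.max_nfev)
            except Exception:
                continue
            rn_i = float(np.linalg.norm(sol.fun))
            pn_i = float(np.linalg.norm(sol.x))
            if best is None or (rn_i, pn_i) < (best[0], best[1]):
                best = (rn_i, pn_i, sol.x)
        if best is None:
            raise FitFailureError("no multistart converged for free phases")
        rn, _, logk = best
        rates = np.concatenate([preset, np.exp(logk)])
        coef, _ = _varpro_residual(t, y, rates)
        amps, offset = coef[1:], float(coef[0])

    order = np.argsort(rates)[::-1]
    return ExponentialFit(
        n_phases=n_total,
        amplitudes=np.asarray(amps)[order],
        k_obs=np.asarray(rates)[order],
        offset=offset,
        residual_norm=rn,
        converged=True,
    )
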