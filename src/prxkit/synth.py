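"""Synthetic instrument data for every stage of the pipeline.

Generates stopped-flow fluorescence traces, NADPH A340 progress curves,
ratiometric plate-reader tables and sampled decamer populations, all
deterministic given a seed, so the inference stages can be exercised
end-to-end without instrument data.  Noise is additive Gaussian with a
standard deviation expressed as a fraction of the signal range
(homoscedastic); generating parameters and the seed are embedded in each
table's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import linregress

from . import ring
from .errors import InvalidParameterError
from .scheme import build_scheme, simulate_trace


def default_rates() -> dict:
    """Literature rate constants for the yeast Tsa1/Tsa2 system."""
    with resources.files("prxkit.data").joinpath("default_rates.yaml").open() as fh:
        return yaml.safe_load(fh)


#: default co-substrate designs (M): chosen once as the study conditions —
#: pseudo-first-order excess over 1 uM (oxidation) or 2 uM (reduction) enzyme
OXIDATION_H2O2 = tuple(c * 1e-6 for c in (10, 20, 40, 60, 80, 100))
REDUCTION_TRX1 = tuple(c * 1e-6 for c in (20, 40, 60, 80, 100, 120))
HETERO_H2O2 = tuple(c * 1e-6 for c in (10, 20, 30, 40, 50, 60, 80, 100))


@dataclass
class GeneratorConfig:
    """Shared knobs of all generators; the seed is part of the conditions."""

    seed: int = 0
    noise_sd: float = 0.01  # fraction of the per-trace signal range
    concentrations: tuple = ()  # M; empty -> per-mode default
    replicates: int = 3
    rates: dict = field(default_factory=dict)  # empty -> default_rates() entry
    enzyme_conc: float | None = None  # M; None -> per-mode default
    decamer_p: float = 0.2  # probability a subunit is type 2

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not 0 <= self.decamer_p <= 1:
            raise InvalidParameterError("decamer_p must be in [0, 1]")
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")


def fast_eigenvalue(a: float, k_rev: float, k2red: float) -> float:
    """Fast relaxation rate of SS <-> MIX -> RED at pumping rate a = k1red*[Trx1]."""
    s = a + k_rev + k2red
    p = k2red * a
    return 0.5 * (s + np.sqrt(s * s - 4.0 * p))


def reverse_rate_for_intercept(
    intercept: float, k1red: float, k2red: float, trx_concs
) -> float:
    """Reverse rate that makes the k_obs,1 regression intercept equal ``intercept``.

    The printed intercept of k_obs,1 versus [Trx1] is an observable; in the
    reversible first reduction step the fast eigenvalue equals
    a + k_rev + k2red only asymptotically, so the microscopic k_rev is found
    by root-finding on the noiseless eigenvalue regression over the actual
    concentration design.
    """
    a = k1red * np.asarray(list(trx_concs), dtype=float)
    if a.size < 3:
        raise InvalidParameterError("need >= 3 Trx1 concentrations")

    def intercept_of(k_rev: float) -> float:
        y = fast_eigenvalue(a, k_rev, k2red)
        return linregress(a, y).intercept

    lo, hi = 0.0, max(2.0 * intercept, intercept + 5.0 * k2red)
    if intercept_of(lo) > intercept:
        raise InvalidParameterError(
            f"intercept {intercept} s^-1 unreachable: design curvature alone exceeds it"
        )
    return float(brentq(lambda k: intercept_of(k) - intercept, lo, hi, xtol=1e-10))


def _time_grid(mode: str) -> np.ndarray:
    # log-spaced from 0.1 ms (instrument dead-time scale), covering the
    # fastest phase through ~5 time constants of the slowest
    if mode == "oxidation":
        return np.geomspace(1e-4, 2.0, 1000)
    if mode == "hetero_oxidation":
        return np.geomspace(1e-4, 2.0, 2000)
    return np.geomspace(2e-4, 10.0, 4000)


def resolve_reduction_params(rates: dict, trx_concs) -> dict:
    """Replace a ``kobs_intercept`` entry by the calibrated ``k_rev``."""
    params = dict(rates)
    if "kobs_intercept" in params:
        params["k_rev"] = reverse_rate_for_intercept(
            params.pop("kobs_intercept"), params["k1red"], params["k2red"], trx_concs
        )
    return params


def gen_stopped_flow(
    config: GeneratorConfig,
    mode: str = "oxidation",
    rate_key: str | None = None,
    t_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Stopped-flow trace table: replicate, conc_M, time_s, signal.

    ``rate_key`` selects a parameter set from the bundled defaults
    (e.g. ``"tsa2_oxidation"``); ``config.rates`` overrides it.  Metadata
    (seed, generating constants, enzyme concentration) lives in ``df.attrs``.
    """
    if mode == "oxidation":
        concs = config.concentrations or OXIDATION_H2O2
        enzyme = config.enzyme_conc if config.enzyme_conc is not None else 1e-6
        rates = config.rates or default_rates()[rate_key or "tsa2_oxidation"]
        params = dict(rates)
    elif mode == "reduction":
        concs = config.concentrations or REDUCTION_TRX1
        enzyme = config.enzyme_conc if config.enzyme_conc is not None else 2e-6
        rates = config.rates or default_rates()[rate_key or "tsa2_reduction"]
        params = resolve_reduction_params(rates, concs)
    elif mode == "hetero_oxidation":
        concs = config.concentrations or HETERO_H2O2
        enzyme = config.enzyme_conc if config.enzyme_conc is not None else 1e-6
        rates = config.rates or default_rates()[rate_key or "hetero_oxidation"]
        params = dict(rates)
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")

    t = _time_grid(mode) if t_grid is None else np.asarray(t_grid, float)
    scheme = build_scheme(mode, params)
    rng = np.random.default_rng(config.seed)

    rows = []
    for conc in concs:
        trace = simulate_trace(scheme, enzyme, conc, t)
        span = float(np.ptp(trace.signal))
        for rep in range(config.replicates):
            noise = rng.normal(0.0, config.noise_sd * span, size=t.size)
            rows.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "conc_M": conc,
                        "time_s": t,
                        "signal": trace.signal + noise,
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    df.attrs = {
        "seed": config.seed,
        "mode": mode,
        "noise_sd": config.noise_sd,
        "enzyme_conc_M": enzyme,
        "generating_rates": params,
    }
    return df


def gen_steady_state(
    config: GeneratorConfig,
    v_true: float = 10e-6 / 60.0,  # M/s; 10 uM/min sits inside the working band
    nadph0: float = 150e-6,  # M
    baseline_s: float = 30.0,
    total_s: float = 120.0,
    drift_per_s: float = 0.0,
    a0: float = 1.0,
    dt: float = 0.5,
) -> pd.DataFrame:
    """NADPH A340 progress curve: flat-plus-drift baseline, then consumption.

    The post-start rate is ``v_true * N/(N + K_N)`` with K_N = 5 uM, so the
    curve is initially linear and rolls off as NADPH depletes.  The true
    rate is recorded in ``df.attrs``.
    """
    if v_true < 0 or nadph0 <= 0:
        raise InvalidParameterError("v_true must be >= 0 and nadph0 > 0")
    eps_M = 6.22e3  # M^-1 cm^-1
    k_n = 5e-6
    # normalize the soft-saturation factor so the rate at reaction start
    # equals v_true exactly
    sat0 = nadph0 / (nadph0 + k_n)
    t = np.arange(0.0, total_s + dt / 2, dt)
    n = np.empty_like(t)
    level = nadph0
    for i, ti in enumerate(t):
        n[i] = level
        if ti >= baseline_s:
            rate = v_true * (level / (level + k_n)) / sat0
            level = max(level - rate * dt, 0.0)
    a340 = a0 + drift_per_s * t - eps_M * (nadph0 - n)
    rng = np.random.default_rng(config.seed)
    a340 = a340 + rng.normal(0.0, config.noise_sd * max(np.ptp(a340), 1e-12), t.size)
    df = pd.DataFrame({"time_s": t, "a340": a340})
    df.attrs = {
        "seed": config.seed,
        "v_true_M_per_s": v_true,
        "baseline_s": baseline_s,
        "drift_per_s": drift_per_s,
        "noise_sd": config.noise_sd,
    }
    return df


#: default plate-reader control intensities (a.u.): the 400-excitation band
#: rises and the 480-excitation band falls upon oxidation
PLATE_CONTROLS = {"I400_red": 100.0, "I400_ox": 300.0, "I480_red": 300.0, "I480_ox": 100.0}


def gen_plate_reader(
    config: GeneratorConfig,
    true_oxd_trajectory,
    time_min: np.ndarray | None = None,
    controls: dict | None = None,
    well: str = "A1",
) -> pd.DataFrame:
    """Ratiometric plate table: well, time_min, channel (400|480), role, intensity.

    Sample intensities interpolate linearly between the reduced and oxidized
    control intensities according to the true OxD trajectory, a construction
    under which the ratiometric OxD formula returns the trajectory exactly
    on noiseless data.
    """
    oxd = np.asarray(list(true_oxd_trajectory), dtype=float)
    if np.any((oxd < 0) | (oxd > 1)):
        raise InvalidParameterError("true OxD trajectory must lie in [0, 1]")
    ctl = dict(PLATE_CONTROLS)
    if controls:
        ctl.update(controls)
    tm = np.arange(oxd.size, dtype=float) * 5.0 if time_min is None else np.asarray(time_min, float)
    if tm.size != oxd.size:
        raise InvalidParameterError("time_min and trajectory lengths differ")

    i400 = ctl["I400_red"] + oxd * (ctl["I400_ox"] - ctl["I400_red"])
    i480 = ctl["I480_red"] + oxd * (ctl["I480_ox"] - ctl["I480_red"])
    rng = np.random.default_rng(config.seed)
    span = max(abs(ctl["I400_ox"] - ctl["I400_red"]), abs(ctl["I480_red"] - ctl["I480_ox"]))

    rows = []
    for t, s400, s480 in zip(tm, i400, i480):
        for channel, role, base in (
            ("400", "sample", s400),
            ("480", "sample", s480),
            ("400", "red", ctl["I400_red"]),
            ("480", "red", ctl["I480_red"]),
            ("400", "ox", ctl["I400_ox"]),
            ("480", "ox", ctl["I480_ox"]),
        ):
            noise = rng.normal(0.0, config.noise_sd * span) if config.noise_sd > 0 else 0.0
            rows.append((well, t, channel, role, base + noise))
    df = pd.DataFrame(rows, columns=["well", "time_min", "channel", "role", "intensity"])
    df.attrs = {"seed": config.seed, "noise_sd": config.noise_sd, "controls": ctl}
    return df


def gen_induction(
    config: GeneratorConfig,
    plateau_fold: float = 5.0,
    t_halfway: float = 20.0,
    n_points: int = 19,
    t_end: float = 90.0,
    f0: float = 100.0,
) -> pd.DataFrame:
    """Fluorescence induction time course rising to ``plateau_fold`` x baseline."""
    if plateau_fold <= 0 or f0 <= 0:
        raise InvalidParameterError("plateau_fold and f0 must be > 0")
    t = np.linspace(0.0, t_end, n_points)
    tau = t_halfway / np.log(2.0)
    f = f0 * (1.0 + (plateau_fold - 1.0) * (1.0 - np.exp(-t / tau)))
    rng = np.random.default_rng(config.seed)
    f = f + rng.normal(0.0, config.noise_sd * np.ptp(f), t.size)
    df = pd.DataFrame({"time_min": t, "fluorescence": f})
    df.attrs = {"seed": config.seed, "plateau_fold": plateau_fold}
    return df


def gen_decamer_population(
    config: GeneratorConfig, n: int, d: int = 5
) -> tuple[list[ring.DecamerConfiguration], dict[int, int]]:
    """Sample ``n`` decamers with independent type-2 subunit incorporation.

    Each of the ``2d`` subunits is type 2 with probability ``config.decamer_p``
    (binomial incorporation — a modeling stand-in for the stoichiometry
    ladder seen on native gels).  Configurations are returned in canonical
    form together with the histogram over type-2 counts.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    group = ring.build_symmetry_group(d)
    labels = (rng.random((n, 2 * d)) < config.decamer_p).astype(int)
    configs = [
        ring.canonical_form(ring.DecamerConfiguration(tuple(int(x) for x in row), d=d), group)
        for row in labels
    ]
    counts = labels.sum(axis=1)
    hist = {int(k): int(c) for k, c in zip(*np.unique(counts, return_counts=True))}
    return configs, hist
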