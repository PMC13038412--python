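"""End-to-end simulate -> fit -> regress protocols.

Each function reproduces one complete stopped-flow analysis chain: generate
noisy traces with the bundled literature constants (or overrides), average
the technical replicates per concentration, fit each averaged trace with the
appropriate number of exponential phases, and reduce the observed rates to
mechanistic constants via the secondary plot.  These are the same chains the
command-line subcommands compose by hand, packaged for parameter-recovery
studies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import IdentifiabilityWarning
from .fit import MultistartConfig, fit_exponentials, secondary_fit
from .scheme import FluorescenceTrace
from .synth import GeneratorConfig, default_rates, gen_stopped_flow


def _fit_averaged(df: pd.DataFrame, n_phases: int, seed: int):
    """Average technical replicates per concentration, fit each mean trace."""
    results = []
    strategy = MultistartConfig(seed=seed)
    for conc, grp in df.groupby("conc_M"):
        mean = grp.groupby("time_s")["signal"].mean()
        trace = FluorescenceTrace(mean.index.to_numpy(), mean.to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IdentifiabilityWarning)
            fit = fit_exponentials(trace, n_phases, strategy)
        results.append((float(conc), fit))
    return results


def oxidation_recovery(
    seed: int,
    rate_key: str = "tsa2_oxidation",
    config: GeneratorConfig | None = None,
) -> dict:
    """Recover oxidation constants from synthetic pseudo-first-order traces.

    Triple-exponential fits per H2O2 concentration; the fastest phase's
    concentration dependence is linear with slope k1ox, while the two
    H2O2-independent phases average to k2ox and k3ox.
    """
    cfg = config or GeneratorConfig(seed=seed)
    df = gen_stopped_flow(cfg, mode="oxidation", rate_key=rate_key)
    fits = _fit_averaged(df, 3, seed)
    first = [(c, f.k_obs[0]) for c, f in fits]
    sec = secondary_fit(first, "linear")
    return {
        "k1ox": sec.slope,
        "k1ox_intercept": sec.intercept,
        "k2ox": float(np.mean([f.k_obs[1] for _, f in fits])),
        "k3ox": float(np.mean([f.k_obs[2] for _, f in fits])),
        "generating": df.attrs["generating_rates"],
    }


def reduction_recovery(
    seed: int,
    rate_key: str = "tsa2_reduction",
    config: GeneratorConfig | None = None,
) -> dict:
    """Recover reduction constants from synthetic Trx1-dependent traces.

    The fastest phase's k_obs rises linearly in [Trx1] with slope k1red and
    a non-zero intercept from the reverse of the mixed-disulfide step; the
    number of fitted phases follows the generating scheme (two, or three
    when the slow dissociation step is present).
    """
    cfg = config or GeneratorConfig(seed=seed)
    rates = cfg.rates or default_rates()[rate_key]
    n_phases = 3 if "k3red" in rates else 2
    df = gen_stopped_flow(cfg, mode="reduction", rate_key=rate_key)
    fits = _fit_averaged(df, n_phases, seed)
    first = [(c, f.k_obs[0]) for c, f in fits]
    sec = secondary_fit(first, "linear")
    out = {
        "k1red": sec.slope,
        "kobs_intercept": sec.intercept,
        "k2red_eigen": float(np.mean([f.k_obs[1] for _, f in fits])),
        "generating": df.attrs["generating_rates"],
    }
    if n_phases == 3:
        out["k3red"] = float(np.mean([f.k_obs[2] for _, f in fits]))
    return out


def hetero_oxidation_recovery(
    seed: int,
    rate_key: str = "hetero_oxidation",
    config: GeneratorConfig | None = None,
) -> dict:
    """Recover hetero-oligomer constants by quadruple-exponential fitting.

    Two parallel oxidation chains (equal subunit fractions) share the
    conformational and disulfide phases: the two fastest fitted rates
    regress on [H2O2] with slopes k1oxA > k1oxB, and the two slowest
    average to the shared k2ox and k3ox.
    """
    cfg = config or GeneratorConfig(seed=seed)
    df = gen_stopped_flow(cfg, mode="hetero_oxidation", rate_key=rate_key)
    fits = _fit_averaged(df, 4, seed)
    fast = [(c, f.k_obs[0]) for c, f in fits]
    second = [(c, f.k_obs[1]) for c, f in fits]
    return {
        "k1oxA": secondary_fit(fast, "linear").slope,
        "k1oxB": secondary_fit(second, "linear").slope,
        "k2ox": float(np.mean([f.k_obs[2] for _, f in fits])),
        "k3ox": float(np.mean([f.k_obs[3] for _, f in fits])),
        "generating": df.attrs["generating_rates"],
    }


__all__ = [
    "oxidation_recovery",
    "reduction_recovery",
    "hetero_oxidation_recovery",
]
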