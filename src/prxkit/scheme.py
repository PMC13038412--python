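"""Kinetic scheme of the 2-Cys peroxiredoxin catalytic cycle and its simulation.

The oxidation half-cycle of a typical 2-Cys peroxiredoxin monitored by
intrinsic tryptophan fluorescence shows three phases: peroxide-dependent
sulfenylation of the peroxidatic cysteine (R -> SOH, second-order in H2O2),
a fully-folded to locally-unfolded conformational change (SOH -> LU), and
intersubunit disulfide formation across the B-type dimer interface
(LU -> SS).  The thioredoxin-dependent reduction half-cycle is modelled as
SS <-> MIX -> RED (+ optional RED -> DISS), where MIX is the enzyme-Trx
mixed disulfide, the reverse rate on the first step produces the non-zero
intercept of k_obs,1 versus [Trx1], and the optional slow step stands for a
Trx-induced decamer dissociation seen for some enzymes.

Under pseudo-first-order conditions (co-substrate clamped in excess) every
scheme here is a linear, time-invariant first-order system; traces are
propagated exactly by matrix exponentials and a closed-form sequential-decay
(Bateman-type) solution is provided as an independent oracle for
irreversible chains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .errors import ConfigurationError, InvalidParameterError, PseudoFirstOrderWarning

#: default fluorescence coefficients (arbitrary units per molar), chosen to
#: reproduce the observed decrease / increase / decrease phase signature of
#: the oxidation half-cycle; only the sign pattern is experimentally
#: constrained, so these are configurable.
DEFAULT_FLUOR = {
    "R": 1.0,
    "SOH": 0.7,
    "LU": 0.95,
    "SS": 0.6,
    "SO2H": 0.65,
    "MIX": 0.95,
    "RED": 1.05,
    "DISS": 1.0,
}

_COSUBSTRATE_TAGS = {"H2O2", "Trx1", None}


@dataclass(frozen=True)
class Transition:
    src: str
    dst: str
    rate: float  # s^-1, or M^-1 s^-1 when a co-substrate tag is present
    cosubstrate: str | None = None


@dataclass
class KineticScheme:
    """Species, transitions and fluorescence coefficients of one half-cycle."""

    species: list[str]
    fluorescence: dict[str, float]
    transitions: list[Transition]
    initial_fractions: dict[str, float]
    mode: str = "custom"

    def __post_init__(self) -> None:
        declared = set(self.species)
        for tr in self.transitions:
            if tr.src not in declared or tr.dst not in declared:
                raise ConfigurationError(
                    f"transition {tr.src}->{tr.dst} references undeclared species"
                )
            if tr.rate < 0:
                raise InvalidParameterError(
                    f"rate for {tr.src}->{tr.dst} must be >= 0, got {tr.rate}"
                )
            if tr.cosubstrate not in _COSUBSTRATE_TAGS:
                raise ConfigurationError(f"unknown co-substrate tag {tr.cosubstrate!r}")
        tot = sum(self.initial_fractions.values())
        if not np.isclose(tot, 1.0, rtol=1e-9):
            raise ConfigurationError(f"initial fractions sum to {tot}, expected 1")

    def rate_matrix(self, cosubstrate_conc: float) -> np.ndarray:
        """First-order rate matrix with the co-substrate clamped constant."""
        idx = {s: i for i, s in enumerate(self.species)}
        M = np.zeros((len(self.species), len(self.species)))
        for tr in self.transitions:
            k = tr.rate * (cosubstrate_conc if tr.cosubstrate is not None else 1.0)
            M[idx[tr.dst], idx[tr.src]] += k
            M[idx[tr.src], idx[tr.src]] -= k
        return M


@dataclass
class FluorescenceTrace:
    """One stopped-flow trace: time (s), signal (a.u.) and run metadata."""

    time: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size != self.signal.size or self.time.size < 2:
            raise InvalidParameterError("time and signal must have equal length >= 2")
        if self.time[0] < 0:
            raise InvalidParameterError("time must start at >= 0")


def _require(params: dict, keys: list[str], mode: str) -> None:
    for key in keys:
        if key not in params:
            raise ConfigurationError(f"mode {mode!r} requires rate constant {key!r}")
        if params[key] < 0:
            raise InvalidParameterError(f"rate constant {key!r} must be >= 0")


def build_scheme(
    mode: str,
    params: dict,
    fluorescence: dict[str, float] | None = None,
    fractions: tuple[float, float] = (0.5, 0.5),
    hyperoxidation: bool = False,
) -> KineticScheme:
    """Assemble the kinetic scheme for one measurement mode.

    Parameters
    ----------
    mode
        ``"oxidation"`` (R -> SOH -> LU -> SS, H2O2-dependent first step),
        ``"reduction"`` (SS <-> MIX -> RED [-> DISS], Trx1-dependent first
        step) or ``"hetero_oxidation"`` (two parallel oxidation chains with
        per-subunit-type k1ox sharing k2ox and k3ox).
    params
        Rate-constant map.  Second-order constants (k1ox, k1oxA, k1oxB,
        k1red) in M^-1 s^-1; first-order constants in s^-1.  ``k3red``
        (reduction) and ``khyp`` (oxidation, with ``hyperoxidation=True``)
        are optional.
    fractions
        Subunit-type fractions (A, B) of the hetero-oligomer; must sum to 1.
    hyperoxidation
        Add the inactivating SOH -> SO2H sink (rate ``khyp`` x [H2O2]),
        emulating sulfinic-acid formation at high peroxide loads.
    """
    fluor = dict(DEFAULT_FLUOR)
    if fluorescence:
        fluor.update(fluorescence)

    if mode == "oxidation":
        _require(params, ["k1ox", "k2ox", "k3ox"], mode)
        species = ["R", "SOH", "LU", "SS"]
        transitions = [
            Transition("R", "SOH", params["k1ox"], "H2O2"),
            Transition("SOH", "LU", params["k2ox"]),
            Transition("LU", "SS", params["k3ox"]),
        ]
        if hyperoxidation:
            _require(params, ["khyp"], mode)
            species.append("SO2H")
            transitions.append(Transition("SOH", "SO2H", params["khyp"], "H2O2"))
        init = {"R": 1.0}
    elif mode == "reduction":
        _require(params, ["k1red", "k_rev", "k2red"], mode)
        species = ["SS", "MIX", "RED"]
        transitions = [
            Transition("SS", "MIX", params["k1red"], "Trx1"),
            Transition("MIX", "SS", params["k_rev"]),
            Transition("MIX", "RED", params["k2red"]),
        ]
        if "k3red" in params:
            species.append("DISS")
            transitions.append(Transition("RED", "DISS", params["k3red"]))
        init = {"SS": 1.0}
    elif mode == "hetero_oxidation":
        _require(params, ["k1oxA", "k1oxB", "k2ox", "k3ox"], mode)
        fA, fB = fractions
        if fA < 0 or fB < 0 or not np.isclose(fA + fB, 1.0):
            raise InvalidParameterError(f"fractions must be >= 0 and sum to 1, got {fractions}")
        species, transitions = [], []
        for tag, k1 in (("A", params["k1oxA"]), ("B", params["k1oxB"])):
            sp = [f"{s}_{tag}" for s in ("R", "SOH", "LU", "SS")]
            species += sp
            transitions += [
                Transition(sp[0], sp[1], k1, "H2O2"),
                Transition(sp[1], sp[2], params["k2ox"]),
                Transition(sp[2], sp[3], params["k3ox"]),
            ]
        for tag in ("A", "B"):
            for s in ("R", "SOH", "LU", "SS"):
                fluor.setdefault(f"{s}_{tag}", fluor[s])
        init = {"R_A": fA, "R_B": fB}
    else:
        raise ConfigurationError(f"unknown scheme mode {mode!r}")

    return KineticScheme(
        species=species,
        fluorescence={s: fluor[s] for s in species},
        transitions=transitions,
        initial_fractions=init,
        mode=mode,
    )


def simulate_concentrations(
    scheme: KineticScheme,
    enzyme_conc: float,
    cosubstrate_conc: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Species concentrations (M), shape (n_species, n_times).

    The linear system c' = M c is propagated step-by-step with matrix
    exponentials, which is exact (to round-off) for a time-invariant system.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise InvalidParameterError("t_grid must be strictly increasing with >= 2 points")
    if enzyme_conc < 0 or cosubstrate_conc < 0:
        raise InvalidParameterError("concentrations must be >= 0")
    uses_cosubstrate = any(tr.cosubstrate for tr in scheme.transitions)
    if uses_cosubstrate and cosubstrate_conc < 10 * enzyme_conc:
        warnings.warn(
            f"co-substrate ({cosubstrate_conc:g} M) below tenfold excess over enzyme "
            f"({enzyme_conc:g} M); pseudo-first-order assumption is weak",
            PseudoFirstOrderWarning,
            stacklevel=2,
        )
    M = scheme.rate_matrix(cosubstrate_conc)
    c0 = np.array(
        [enzyme_conc * scheme.initial_fractions.get(s, 0.0) for s in scheme.species]
    )
    out = np.empty((len(scheme.species), t.size))
    c = c0.copy()
    t_prev = 0.0
    # cache propagators: log-spaced grids repeat very few distinct steps only
    # when uniform, so key on the rounded dt
    cache: dict[float, np.ndarray] = {}
    for i, ti in enumerate(t):
        dt = ti - t_prev
        if dt > 0:
            P = cache.get(dt)
            if P is None:
                P = expm(M * dt)
                cache[dt] = P
            c = P @ c
        out[:, i] = c
        t_prev = ti
    return out


def simulate_trace(
    scheme: KineticScheme,
    enzyme_conc: float,
    cosubstrate_conc: float,
    t_grid: np.ndarray,
    metadata: dict | None = None,
) -> FluorescenceTrace:
    """Noise-free fluorescence trace: signal(t) = sum_s coef_s * c_s(t)."""
    conc = simulate_concentrations(scheme, enzyme_conc, cosubstrate_conc, t_grid)
    coefs = np.array([scheme.fluorescence[s] for s in scheme.species])
    signal = coefs @ conc
    meta = {
        "mode": scheme.mode,
        "enzyme_conc_M": enzyme_conc,
        "cosubstrate_conc_M": cosubstrate_conc,
    }
    if metadata:
        meta.update(metadata)
    return FluorescenceTrace(time=np.asarray(t_grid, float), signal=signal, metadata=meta)


def _terms_convolve(
    terms: list[tuple[float, int, float]], k_in: float, k_out: float
) -> list[tuple[float, int, float]]:
    """Convolution step of the sequential-decay algebra.

    Given c_prev(t) = sum a * t^p * exp(-r t), return the same representation
    of k_in * integral_0^t exp(-k_out (t-s)) c_prev(s) ds, merging the
    confluent (r == k_out) case exactly into t^(p+1) terms.
    """
    out: dict[tuple[int, float], float] = {}

    def add(a: float, p: int, r: float) -> None:
        key = (p, r)
        out[key] = out.get(key, 0.0) + a

    for a, p, r in terms:
        c = r - k_out
        scale = max(abs(r), abs(k_out), 1.0)
        if abs(c) <= 1e-12 * scale:
            add(k_in * a / (p + 1), p + 1, k_out)
        else:
            fact_p = math.factorial(p)
            add(k_in * a * fact_p / c ** (p + 1), 0, k_out)
            for j in range(p + 1):
                add(-k_in * a * fact_p / math.factorial(j) / c ** (p - j + 1), j, r)
    return [(a, p, r) for (p, r), a in out.items() if a != 0.0]


def analytic_chain_solution(rates: list[float], t: np.ndarray) -> np.ndarray:
    """Closed-form species fractions of an irreversible sequential chain.

    ``rates[i]`` is the first-order decay rate of species ``i``; one final
    absorbing species is appended, so the result has ``len(rates) + 1`` rows.
    Repeated rates are handled exactly through the confluent ``t^p e^{-kt}``
    terms rather than by perturbation, so the equal-rate limit (e.g. the
    classical ``k t e^{-kt}`` second species) is reproduced to round-off.
    """
    rates = [float(k) for k in rates]
    if any(k < 0 for k in rates):
        raise InvalidParameterError("chain rates must be >= 0")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    n_species = len(rates) + 1
    all_rates = rates + [0.0]

    species_terms: list[list[tuple[float, int, float]]] = []
    terms: list[tuple[float, int, float]] = [(1.0, 0, all_rates[0])]
    species_terms.append(terms)
    for i in range(1, n_species):
        terms = _terms_convolve(terms, all_rates[i - 1], all_rates[i])
        species_terms.append(terms)

    out = np.zeros((n_species, t.size))
    for i, trm in enumerate(species_terms):
        for a, p, r in trm:
            out[i] += a * t**p * np.exp(-r * t)
    return out
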