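"""Kinetic scheme construction, exact chain solution, and trace simulation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from prxkit import (
    analytic_chain_solution,
    build_scheme,
    simulate_concentrations,
    simulate_trace,
)
from prxkit.errors import (
    ConfigurationError,
    InvalidParameterError,
    PseudoFirstOrderWarning,
)

OX = {"k1ox": 1.3e7, "k2ox": 45.0, "k3ox": 3.6}
RED = {"k1red": 3.9e6, "k_rev": 10.0, "k2red": 10.0}


def integrate_chain_numerically(rates, t):
    """Independent stiff ODE integration of the sequential chain."""
    n = len(rates) + 1

    def rhs(_, c):
        dc = np.zeros(n)
        for i, k in enumerate(rates):
            flux = k * c[i]
            dc[i] -= flux
            dc[i + 1] += flux
        return dc

    c0 = np.zeros(n)
    c0[0] = 1.0
    sol = solve_ivp(rhs, (0, t[-1]), c0, t_eval=t, method="LSODA", rtol=1e-11, atol=1e-14)
    return sol.y


class TestAnalyticChain:
    @pytest.mark.parametrize(
        "rates",
        [[1.0, 2.0], [5.0, 0.5, 0.05], [1.0, 1.0], [2.0, 2.0, 2.0], [130.0, 45.0, 3.6]],
    )
    def test_matches_independent_integration(self, rates):
        t = np.linspace(0.01, 5.0 / min(r for r in rates if r > 0), 40)
        exact = analytic_chain_solution(rates, t)
        numeric = integrate_chain_numerically(rates, t)
        assert np.allclose(exact, numeric, rtol=1e-7, atol=1e-10)

    def test_equal_rate_limit_is_t_exp(self):
        frac = analytic_chain_solution([1.0, 1.0], np.array([1.0]))
        assert frac[1, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_stalled_chain_accumulates_second_species(self):
        frac = analytic_chain_solution([3.0, 0.0], np.array([50.0]))
        assert frac[1, 0] == pytest.approx(1.0, abs=1e-12)
        assert frac[2, 0] == pytest.approx(0.0, abs=1e-12)

    def test_fractions_sum_to_one(self, rng):
        for _ in range(20):
            rates = list(rng.uniform(0.01, 100.0, size=rng.integers(1, 4)))
            t = np.geomspace(1e-3, 10.0, 30)
            frac = analytic_chain_solution(rates, t)
            assert np.allclose(frac.sum(axis=0), 1.0, atol=1e-10)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            analytic_chain_solution([1.0, -0.1], np.array([1.0]))


class TestBuildScheme:
    def test_oxidation_structure(self):
        s = build_scheme("oxidation", OX)
        assert s.species == ["R", "SOH", "LU", "SS"]
        assert len(s.transitions) == 3
        assert s.transitions[0].cosubstrate == "H2O2"

    def test_reduction_without_dissociation_has_two_forward_steps(self):
        s = build_scheme("reduction", RED)
        assert s.species == ["SS", "MIX", "RED"]
        forward = [tr for tr in s.transitions if tr.src != "MIX" or tr.dst != "SS"]
        reverse = [tr for tr in s.transitions if (tr.src, tr.dst) == ("MIX", "SS")]
        assert len(forward) == 2 and len(reverse) == 1

    def test_reduction_with_dissociation_adds_species(self):
        s = build_scheme("reduction", dict(RED, k3red=0.6))
        assert s.species[-1] == "DISS"
        assert len(s.transitions) == 4

    def test_hetero_conserves_initial_population(self):
        s = build_scheme(
            "hetero_oxidation",
            {"k1oxA": 6.1e7, "k1oxB": 2.8e7, "k2ox": 45.0, "k3ox": 3.6},
            fractions=(0.3, 0.7),
        )
        assert sum(s.initial_fractions.values()) == pytest.approx(1.0)
        assert len(s.species) == 8

    def test_missing_constant_names_symbol(self):
        with pytest.raises(ConfigurationError, match="k3ox"):
            build_scheme("oxidation", {"k1ox": 1e7, "k2ox": 45.0})

    def test_negative_constant_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_scheme("oxidation", dict(OX, k2ox=-1.0))

    def test_hyperoxidation_sink_off_by_default(self):
        assert "SO2H" not in build_scheme("oxidation", OX).species
        s = build_scheme("oxidation", dict(OX, khyp=1e4), hyperoxidation=True)
        assert "SO2H" in s.species


class TestSimulateTrace:
    def test_mass_conservation(self):
        for mode, params, conc in [
            ("oxidation", OX, 1e-4),
            ("reduction", dict(RED, k3red=0.6), 1e-4),
            ("hetero_oxidation", {"k1oxA": 6.1e7, "k1oxB": 2.8e7, "k2ox": 45.0, "k3ox": 3.6}, 1e-4),
        ]:
            scheme = build_scheme(mode, params)
            t = np.geomspace(1e-4, 1.0, 200)
            c = simulate_concentrations(scheme, 1e-6, conc, t)
            assert np.allclose(c.sum(axis=0), 1e-6, rtol=1e-9)

    def test_single_step_decay_is_exact_exponential(self):
        scheme = build_scheme("oxidation", {"k1ox": 1e7, "k2ox": 0.0, "k3ox": 0.0})
        t = np.linspace(0.001, 0.5, 100)
        h2o2 = 2e-5
        trace = simulate_trace(scheme, 1e-6, h2o2, t)
        # log-linear decay of the R-state contribution
        r_frac = simulate_concentrations(scheme, 1e-6, h2o2, t)[0] / 1e-6
        slope = np.polyfit(t, np.log(r_frac), 1)[0]
        assert slope == pytest.approx(-1e7 * h2o2, rel=1e-6)
        assert np.all(np.diff(trace.signal) <= 0) and trace.signal[0] > trace.signal[-1]

    def test_all_rates_zero_gives_constant_signal(self):
        scheme = build_scheme("oxidation", {"k1ox": 0.0, "k2ox": 0.0, "k3ox": 0.0})
        trace = simulate_trace(scheme, 1e-6, 1e-4, np.linspace(0.0, 1.0, 20))
        assert np.allclose(trace.signal, trace.signal[0], rtol=1e-12)

    @pytest.mark.parametrize(
        "params,h2o2",
        [
            (OX, 2e-5),
            ({"k1ox": 1e8, "k2ox": 45.0, "k3ox": 45.0}, 1e-5),  # repeated rates
            ({"k1ox": 5e6, "k2ox": 0.5, "k3ox": 200.0}, 1e-4),
        ],
    )
    def test_integrator_matches_bateman_oracle(self, params, h2o2):
        scheme = build_scheme("oxidation", params)
        t = np.geomspace(1e-4, 2.0, 150)
        enzyme = 1e-7
        conc = simulate_concentrations(scheme, enzyme, h2o2, t)
        rates = [params["k1ox"] * h2o2, params["k2ox"], params["k3ox"]]
        exact = analytic_chain_solution(rates, t)
        assert np.allclose(conc / enzyme, exact, rtol=1e-8, atol=1e-12)

    def test_pseudo_first_order_linearity(self):
        scheme = build_scheme("oxidation", OX)
        t = np.geomspace(1e-4, 0.5, 100)

        def fastest_rate(h2o2):
            r = simulate_concentrations(scheme, 1e-9, h2o2, t)[0] / 1e-9
            return -np.polyfit(t, np.log(r), 1)[0]

        assert fastest_rate(4e-5) == pytest.approx(2 * fastest_rate(2e-5), rel=1e-6)

    def test_low_excess_warns(self):
        scheme = build_scheme("oxidation", OX)
        with pytest.warns(PseudoFirstOrderWarning):
            simulate_trace(scheme, 1e-6, 5e-6, np.linspace(0.001, 1.0, 10))

    def test_non_increasing_grid_rejected(self):
        scheme = build_scheme("oxidation", OX)
        with pytest.raises(InvalidParameterError):
            simulate_trace(scheme, 1e-6, 1e-4, np.array([0.0, 0.1, 0.1]))
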