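"""Utilities, discounts and choice probabilities of the model family.

Includes a scalar per-trial oracle reimplementation of the utility
equations, used to cross-check the vectorized path.
"""

import math

import numpy as np
import pandas as pd
import pytest

import motivecocktail as mc
from motivecocktail import models as mm

from conftest import random_motive_params


def scalar_utilities(params, scenario, x1, x2, x3, cost, ratio):
    """Loop-free-standing oracle: term-by-term utility evaluation."""
    if scenario == "punishment":
        x1p, x2p = x1 - ratio * cost, x2
    else:
        x1p, x2p = x1, x2 + ratio * cost
    x3p = x3 - cost
    d_no = 2.0 / (1.0 + math.exp(params["eta_no"] * cost / 50.0))
    d_yes = 2.0 / (1.0 + math.exp(params["eta_yes"] * cost / 50.0))
    u_no = (x3 - params["gamma"] * max(x1 - x2, 0) * d_no
            - params["alpha"] * (max(x1 - x3, 0) + max(x2 - x3, 0))
            - params["beta"] * (max(x3 - x1, 0) + max(x3 - x2, 0))
            + params["omega"] * (x1 + x2)
            + params["kappa"] * max(x2 - x1, 0))
    u_yes = (x3p - params["gamma"] * max(x1p - x2p, 0) * d_yes
             - params["alpha"] * (max(x1p - x3p, 0) + max(x2p - x3p, 0))
             - params["beta"] * (max(x3p - x1p, 0) + max(x3p - x2p, 0))
             + params["omega"] * (x1p + x2p)
             + params["kappa"] * max(x2p - x1p, 0))
    return u_no, u_yes


class TestPayoffTransitions:
    def test_worked_punishment_example(self):
        ps = mc.post_intervention_payoffs("punishment", 70, 30, 50, 10, 1.5)
        assert (ps.x1p, ps.x2p, ps.x3p) == (55, 30, 40)

    def test_worked_helping_example(self):
        ps = mc.post_intervention_payoffs("helping", 88, 12, 50, 20, 3.0)
        assert (ps.x1p, ps.x2p, ps.x3p) == (88, 72, 30)

    def test_zero_cost_identity_and_conservation(self):
        for scen in ("punishment", "helping"):
            ps = mc.post_intervention_payoffs(scen, 60, 40, 50, 0, 3.0)
            assert (ps.x1p, ps.x2p, ps.x3p) == (60, 40, 50)
        # helping never changes x1; punishment never changes x2
        assert mc.post_intervention_payoffs("helping", 90, 10, 50, 50, 3.0).x1p == 90
        assert mc.post_intervention_payoffs("punishment", 90, 10, 50, 50, 3.0).x2p == 10

    def test_payoffs_may_go_negative(self):
        ps = mc.post_intervention_payoffs("punishment", 50, 50, 50, 50, 3.0)
        assert ps.x1p == -100  # no flooring


class TestInequalityDiscount:
    def test_unit_at_zero_arguments(self):
        assert mc.inequality_discount(0.0, 30.0) == 1.0
        assert mc.inequality_discount(17.3, 0.0) == 1.0

    def test_extreme_value(self):
        assert mc.inequality_discount(20, 50) == pytest.approx(2 / (1 + math.exp(20)))
        assert mc.inequality_discount(20, 50) == pytest.approx(4.12e-9, rel=1e-2)

    def test_strictly_decreasing_and_bounded(self):
        etas = np.linspace(0, 20, 25)
        vals = mc.inequality_discount(etas, 30.0)
        assert np.all(np.diff(vals) < 0)
        assert np.all((vals > 0) & (vals <= 1))
        costs = np.linspace(0, 50, 25)
        vals = mc.inequality_discount(5.0, costs)
        assert np.all(np.diff(vals) < 0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mc.inequality_discount(-1.0, 10.0)
        with pytest.raises(ValueError):
            mc.inequality_discount(1.0, -10.0)


class TestUtilities:
    def test_si_utilities_are_endowment_minus_cost(self, session_trials):
        ub = mc.utility_pair("SI", {"lambda": 1.0}, session_trials)
        assert np.allclose(ub.u_no, 50.0)
        assert np.allclose(ub.u_yes, 50.0 - session_trials["cost"])

    def test_cocktail_worked_example(self, cocktail_params):
        tr = pd.DataFrame({"scenario": ["punishment"], "x1": [70], "x2": [30],
                           "x3": [50], "cost": [10], "ratio": [1.5]})
        ub = mc.utility_pair("cocktail", cocktail_params, tr)
        assert ub.u_no[0] == pytest.approx(37.9933, abs=1e-4)
        assert ub.u_yes[0] == pytest.approx(35.9672, abs=1e-4)

    def test_nested_collapse_chain(self, session_trials):
        """Each model equals the next richer model with added params at 0."""
        rng = np.random.default_rng(0)
        chain = list(mc.UTILITY_MODELS)
        for lean, rich in zip(chain[:-1], chain[1:]):
            for _ in range(20):
                params = random_motive_params(rng, lean)
                rich_params = dict(params)
                for extra in set(mm.MODEL_PARAMS[rich]) - set(mm.MODEL_PARAMS[lean]):
                    rich_params[extra] = 0.0
                a = mc.utility_pair(lean, params, session_trials)
                b = mc.utility_pair(rich, rich_params, session_trials)
                np.testing.assert_allclose(a.u_no, b.u_no, atol=1e-12)
                np.testing.assert_allclose(a.u_yes, b.u_yes, atol=1e-12)

    def test_vectorized_matches_scalar_oracle(self, session_trials):
        rng = np.random.default_rng(1)
        for _ in range(10):
            params = random_motive_params(rng, "cocktail")
            ub = mc.utility_pair("cocktail", params, session_trials)
            for i in (0, 57, 123, 299):
                row = session_trials.iloc[i]
                u_no, u_yes = scalar_utilities(params, row["scenario"],
                                               row["x1"], row["x2"], row["x3"],
                                               row["cost"], row["ratio"])
                assert ub.u_no[i] == pytest.approx(u_no, abs=1e-10)
                assert ub.u_yes[i] == pytest.approx(u_yes, abs=1e-10)

    def test_non_utility_models_rejected(self, session_trials):
        with pytest.raises(ValueError):
            mc.utility_pair("baseline", {"q": 0.5}, session_trials)
        with pytest.raises(ValueError):
            mc.utility_pair("simple_response", {}, session_trials)


class TestChoiceProbability:
    def test_lambda_zero_gives_half(self, session_trials):
        rng = np.random.default_rng(2)
        for model in mc.UTILITY_MODELS[:-1]:  # exclude lapse variant
            params = random_motive_params(rng, model)
            params["lambda"] = 0.0
            p = mc.choice_probability(model, params, session_trials)
            assert np.allclose(p, 0.5)

    def test_si_hand_value(self):
        tr = pd.DataFrame({"scenario": ["punishment"], "x1": [70], "x2": [30],
                           "x3": [50], "cost": [10], "ratio": [1.5]})
        p = mc.choice_probability("SI", {"lambda": 1.0}, tr)
        assert p[0] == pytest.approx(1 / (1 + math.exp(10)), rel=1e-12)

    def test_baseline_returns_q(self, session_trials):
        p = mc.choice_probability("baseline", {"q": 0.3}, session_trials)
        assert np.allclose(p, 0.3)

    def test_lapse_endpoints(self, session_trials, cocktail_params):
        params = dict(cocktail_params, p_min=0.1, p_max=0.2)
        # force pre-lapse P to 0 and 1 via extreme lambda and utilities
        params.update({"lambda": 10.0, "gamma": 10.0, "eta_no": 0.0,
                       "eta_yes": 20.0, "alpha": 0, "beta": 0, "omega": 0,
                       "kappa": 0})
        p = mc.choice_probability("cocktail_lapse", params, session_trials)
        assert np.all(p >= 0.1 - 1e-12)
        assert np.all(p <= 0.8 + 1e-12)
        hi = session_trials["split"] == 90
        assert p[hi.to_numpy() & (session_trials["cost"] == 10).to_numpy()].max() \
            == pytest.approx(0.8, abs=1e-3)

    def test_softmax_symmetry(self):
        u = np.array([3.0]), np.array([7.0])
        p = mm.softmax_yes(0.7, u[0], u[1])
        q = mm.softmax_yes(0.7, u[1], u[0])
        assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_si_monotone_decreasing_in_cost(self):
        tr = pd.DataFrame({"scenario": "punishment", "x1": 70, "x2": 30,
                           "x3": 50, "cost": [10, 20, 30, 40, 50],
                           "ratio": 1.5})
        p = mc.choice_probability("SI", {"lambda": 0.3}, tr)
        assert np.all(np.diff(p) < 0)

    def test_numerical_stability_extreme_lambda(self, session_trials):
        params = {"lambda": 10.0, "alpha": 10.0, "beta": 10.0, "gamma": 10.0,
                  "omega": 10.0, "kappa": -10.0, "eta_no": 0.0, "eta_yes": 0.0}
        p = mc.choice_probability("cocktail", params, session_trials)
        assert np.all(np.isfinite(p))
        assert np.all((p >= 0) & (p <= 1))

    def test_simple_response_lapse_and_bounds(self, session_trials):
        params = {"temperature": 2.0, "b_scenario": 1.0, "b_inequality": -1.0,
                  "b_cost": 1.0, "b_ratio": -0.5, "p_min": 0.05, "p_max": 0.1}
        p = mc.choice_probability("simple_response", params, session_trials)
        assert np.all((p >= 0.05 - 1e-12) & (p <= 0.9 + 1e-12))


def test_param_json_round_trip(cocktail_params):
    obj = mm.params_to_json("cocktail", cocktail_params)
    model, params = mm.params_from_json(obj)
    assert model == "cocktail"
    assert params == {k: float(v) for k, v in cocktail_params.items()}


def test_free_parameter_counts():
    expected = {"baseline": 1, "SI": 1, "SI_SCI": 3, "SI_SCI_VCI": 4,
                "SI_SCI_VCI_EC": 5, "SI_SCI_VCI_EC_RP": 6, "cocktail": 8,
                "cocktail_lapse": 10, "simple_response": 7}
    assert {m: mm.n_free_params(m) for m in mc.MODEL_ORDER} == expected
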