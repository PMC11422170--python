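"""The nine-choice-model family for intervene-or-watch decisions.

The family nests a baseline Bernoulli responder, a pure self-interest (SI)
softmax model, and successively richer socioeconomic utility models built on
Fehr-Schmidt-style inequality aversion:

* SCI - self-centered inequality: weights ``alpha`` (disadvantageous,
  other richer than self) and ``beta`` (advantageous, self richer).
* VCI - victim-centered disadvantageous inequality: weight ``gamma`` on
  max(x1 - x2, 0), the transgressor-over-victim payoff gap.
* EC - efficiency concern: weight ``omega`` on the other parties' total
  payoff x1 + x2.
* RP - reversal preference: signed weight ``kappa`` on max(x2 - x1, 0),
  the victim ending up richer than the transgressor.
* ID - inequality discounting: cost-dependent attenuation of the VCI term,
  delta = 2 / (1 + exp(eta * cost / 50)), with separate rates ``eta_no``
  (inaction) and ``eta_yes`` (action).

The full seven-motive model ("motive cocktail") includes all terms; a lapse
variant bounds the choice probability between ``p_min`` and ``1 - p_max``;
and a simple-response model maps a linear combination of the manipulated
variables straight to choice probability, bypassing utilities.

Choices follow a softmax of the utility difference with inverse temperature
``lambda``: P(yes) = 1 / (1 + exp(lambda * (U_no - U_yes))).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Model registry

MOTIVE_PARAM_NAMES: Tuple[str, ...] = (
    "lambda", "alpha", "beta", "gamma", "omega", "kappa",
    "eta_no", "eta_yes", "p_min", "p_max",
)

MOTIVE_BOUNDS: Dict[str, Tuple[float, float]] = {
    "lambda": (0.0, 10.0),
    "alpha": (0.0, 10.0),
    "beta": (0.0, 10.0),
    "gamma": (0.0, 10.0),
    "omega": (0.0, 10.0),
    "kappa": (-10.0, 10.0),
    "eta_no": (0.0, 20.0),
    "eta_yes": (0.0, 20.0),
    "p_min": (0.0, 0.5),
    "p_max": (0.0, 0.5),
}

SIMPLE_RESPONSE_BOUNDS: Dict[str, Tuple[float, float]] = {
    "temperature": (0.0, 10.0),
    "b_scenario": (-10.0, 10.0),
    "b_inequality": (-10.0, 10.0),
    "b_cost": (-10.0, 10.0),
    "b_ratio": (-10.0, 10.0),
    "p_min": (0.0, 0.5),
    "p_max": (0.0, 0.5),
}

#: Free parameters of each model, in optimization order.
MODEL_PARAMS: Dict[str, Tuple[str, ...]] = {
    "baseline": ("q",),
    "SI": ("lambda",),
    "SI_SCI": ("lambda", "alpha", "beta"),
    "SI_SCI_VCI": ("lambda", "alpha", "beta", "gamma"),
    "SI_SCI_VCI_EC": ("lambda", "alpha", "beta", "gamma", "omega"),
    "SI_SCI_VCI_EC_RP": ("lambda", "alpha", "beta", "gamma", "omega", "kappa"),
    "cocktail": ("lambda", "alpha", "beta", "gamma", "omega", "kappa",
                 "eta_no", "eta_yes"),
    "cocktail_lapse": ("lambda", "alpha", "beta", "gamma", "omega", "kappa",
                       "eta_no", "eta_yes", "p_min", "p_max"),
    "simple_response": ("temperature", "b_scenario", "b_inequality",
                        "b_cost", "b_ratio", "p_min", "p_max"),
}

MODEL_ORDER: Tuple[str, ...] = tuple(MODEL_PARAMS)
UTILITY_MODELS: Tuple[str, ...] = tuple(
    m for m in MODEL_ORDER if m not in ("baseline", "simple_response")
)

_EXP_CLIP = 700.0  # softmax exponent guard


def n_free_params(model: str) -> int:
    return len(MODEL_PARAMS[model])


def param_bounds(model: str) -> List[Tuple[float, float]]:
    """(lower, upper) per free parameter, in optimization order."""
    if model == "baseline":
        return [(0.0, 1.0)]
    if model == "simple_response":
        return [SIMPLE_RESPONSE_BOUNDS[p] for p in MODEL_PARAMS[model]]
    return [MOTIVE_BOUNDS[p] for p in MODEL_PARAMS[model]]


def validate_params(model: str, params: Mapping[str, float]) -> None:
    names = MODEL_PARAMS[model]
    missing = [p for p in names if p not in params]
    if missing:
        raise ValueError(f"model {model!r} missing parameters {missing}")
    for name, (lo, hi) in zip(names, param_bounds(model)):
        v = params[name]
        if not np.isfinite(v) or v < lo or v > hi:
            raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")


def full_motive_vector(model: str, params: Mapping[str, float]) -> Dict[str, float]:
    """Embed a sub-model's parameters into the full motive vector (absent
    motives fixed at 0, so the nested models collapse exactly)."""
    if model not in UTILITY_MODELS:
        raise ValueError(f"{model!r} has no motive-utility parameterization")
    full = {name: 0.0 for name in MOTIVE_PARAM_NAMES}
    for name in MODEL_PARAMS[model]:
        full[name] = float(params[name])
    return full


# --------------------------------------------------------------------------
# Payoffs and trial features


@dataclass(frozen=True)
class PayoffState:
    """Post-intervention payoffs (tokens); may be negative, no flooring."""

    x1p: float
    x2p: float
    x3p: float


def post_intervention_payoffs(scenario: str, x1: float, x2: float, x3: float,
                              cost: float, ratio: float) -> PayoffState:
    """Payoffs if the third party intervenes.

    Punishment reduces the transgressor's payoff by ratio*cost; helping
    increases the victim's payoff by ratio*cost; the intervener pays
    ``cost`` in either scenario.
    """
    if scenario == "punishment":
        return PayoffState(x1 - ratio * cost, x2, x3 - cost)
    if scenario == "helping":
        return PayoffState(x1, x2 + ratio * cost, x3 - cost)
    raise ValueError(f"unknown scenario {scenario!r}")


def inequality_discount(eta: Union[float, np.ndarray],
                        cost: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Inequality-discount factor delta = 2 / (1 + exp(eta * cost / 50)).

    Equals 1 when either argument is 0 and decreases strictly in both;
    value in (0, 1] for nonnegative arguments.
    """
    eta = np.asarray(eta, dtype=float)
    cost = np.asarray(cost, dtype=float)
    if np.any(eta < 0) or np.any(cost < 0):
        raise ValueError("inequality_discount requires eta >= 0 and cost >= 0")
    out = 2.0 / (1.0 + np.exp(np.minimum(eta * cost / 50.0, _EXP_CLIP)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TrialFeatures:
    """Precomputed per-trial motive components (vectorized over trials).

    Caching these makes a likelihood evaluation a handful of axpy
    operations, which matters for multistart fitting.
    """

    cost: np.ndarray
    x3: np.ndarray
    x3p: np.ndarray
    vci_no: np.ndarray     # max(x1 - x2, 0)
    vci_yes: np.ndarray    # max(x1' - x2', 0)
    sci_dis_no: np.ndarray   # sum_j max(x_j - x3, 0)
    sci_dis_yes: np.ndarray
    sci_adv_no: np.ndarray   # sum_j max(x3 - x_j, 0)
    sci_adv_yes: np.ndarray
    ec_no: np.ndarray      # x1 + x2
    ec_yes: np.ndarray
    rp_no: np.ndarray      # max(x2 - x1, 0)
    rp_yes: np.ndarray
    # standardized predictors for the simple-response model
    z_scenario: np.ndarray  # punishment = 1, helping = 0
    z_inequality: np.ndarray
    z_cost: np.ndarray
    z_ratio: np.ndarray

    @property
    def n(self) -> int:
        return self.cost.shape[0]


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v, dtype=float)
    return (v - v.mean()) / sd


def trial_features(trials: pd.DataFrame) -> TrialFeatures:
    """Precompute motive components from a tidy trial table.

    Expects columns scenario, x1, x2, x3, cost, ratio (the session export
    schema).  Simple-response predictors are z-scored over the supplied
    table (scenario dummy-coded punishment=1).
    """
    scen = trials["scenario"].to_numpy()
    x1 = trials["x1"].to_numpy(dtype=float)
    x2 = trials["x2"].to_numpy(dtype=float)
    x3 = trials["x3"].to_numpy(dtype=float)
    cost = trials["cost"].to_numpy(dtype=float)
    ratio = trials["ratio"].to_numpy(dtype=float)

    is_pun = scen == "punishment"
    x1p = np.where(is_pun, x1 - ratio * cost, x1)
    x2p = np.where(is_pun, x2, x2 + ratio * cost)
    x3p = x3 - cost

    def pos(a):
        return np.maximum(a, 0.0)

    return TrialFeatures(
        cost=cost,
        x3=x3,
        x3p=x3p,
        vci_no=pos(x1 - x2),
        vci_yes=pos(x1p - x2p),
        sci_dis_no=pos(x1 - x3) + pos(x2 - x3),
        sci_dis_yes=pos(x1p - x3p) + pos(x2p - x3p),
        sci_adv_no=pos(x3 - x1) + pos(x3 - x2),
        sci_adv_yes=pos(x3p - x1p) + pos(x3p - x2p),
        ec_no=x1 + x2,
        ec_yes=x1p + x2p,
        rp_no=pos(x2 - x1),
        rp_yes=pos(x2p - x1p),
        z_scenario=is_pun.astype(float),
        z_inequality=_zscore(x1 - x2),
        z_cost=_zscore(cost),
        z_ratio=_zscore(ratio),
    )


# --------------------------------------------------------------------------
# Utilities and choice probabilities


@dataclass(frozen=True)
class UtilityBreakdown:
    """Utilities and intermediate quantities for one or many trials."""

    u_no: np.ndarray
    u_yes: np.ndarray
    delta_no: np.ndarray
    delta_yes: np.ndarray

    @property
    def delta_u(self) -> np.ndarray:
        return self.u_yes - self.u_no


def utilities(model: str, params: Mapping[str, float],
              feats: TrialFeatures) -> UtilityBreakdown:
    """U_no and U_yes for any nested utility model.

    Sub-models are evaluated through the full motive vector with absent
    parameters at 0 (delta = 1 when eta = 0), so the collapse is exact.
    """
    th = full_motive_vector(model, params)
    d_no = inequality_discount(th["eta_no"], feats.cost)
    d_yes = inequality_discount(th["eta_yes"], feats.cost)
    u_no = (
        feats.x3
        - th["gamma"] * feats.vci_no * d_no
        - th["alpha"] * feats.sci_dis_no
        - th["beta"] * feats.sci_adv_no
        + th["omega"] * feats.ec_no
        + th["kappa"] * feats.rp_no
    )
    u_yes = (
        feats.x3p
        - th["gamma"] * feats.vci_yes * d_yes
        - th["alpha"] * feats.sci_dis_yes
        - th["beta"] * feats.sci_adv_yes
        + th["omega"] * feats.ec_yes
        + th["kappa"] * feats.rp_yes
    )
    return UtilityBreakdown(u_no=u_no, u_yes=u_yes,
                            delta_no=np.broadcast_to(d_no, u_no.shape),
                            delta_yes=np.broadcast_to(d_yes, u_no.shape))


def utility_pair(model: str, params: Mapping[str, float],
                 trials: pd.DataFrame) -> UtilityBreakdown:
    """Utilities from a tidy trial table (wrapper over :func:`utilities`)."""
    return utilities(model, params, trial_features(trials))


def softmax_yes(lam: float, u_no: np.ndarray, u_yes: np.ndarray) -> np.ndarray:
    z = np.clip(lam * (u_no - u_yes), -_EXP_CLIP, _EXP_CLIP)
    return 1.0 / (1.0 + np.exp(z))


def apply_lapse(p: np.ndarray, p_min: float, p_max: float) -> np.ndarray:
    """Bound P(yes) between p_min and 1 - p_max (lapse / inattention)."""
    return p_min + (1.0 - p_min - p_max) * p


def choice_probability(model: str, params: Mapping[str, float],
                       feats_or_trials: Union[TrialFeatures, pd.DataFrame]) -> np.ndarray:
    """P(yes) per trial for any model in the family."""
    feats = (feats_or_trials if isinstance(feats_or_trials, TrialFeatures)
             else trial_features(feats_or_trials))
    if model == "baseline":
        return np.full(feats.n, float(params["q"]))
    if model == "simple_response":
        lin = (
            params["b_scenario"] * feats.z_scenario
            + params["b_inequality"] * feats.z_inequality
            + params["b_cost"] * feats.z_cost
            + params["b_ratio"] * feats.z_ratio
        )
        z = np.clip(params["temperature"] * lin, -_EXP_CLIP, _EXP_CLIP)
        p = 1.0 / (1.0 + np.exp(z))
        return apply_lapse(p, params["p_min"], params["p_max"])
    ub = utilities(model, params, feats)
    p = softmax_yes(params["lambda"], ub.u_no, ub.u_yes)
    if model == "cocktail_lapse":
        p = apply_lapse(p, params["p_min"], params["p_max"])
    return p


def params_to_json(model: str, params: Mapping[str, float]) -> Dict[str, object]:
    """Flat JSON-serializable record of a parameter vector."""
    return {"model": model,
            "params": {k: float(params[k]) for k in MODEL_PARAMS[model]}}


def params_from_json(obj: Mapping[str, object]) -> Tuple[str, Dict[str, float]]:
    model = str(obj["model"])
    params = {k: float(v) for k, v in dict(obj["params"]).items()}
    validate_params(model, params)
    return model, params
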