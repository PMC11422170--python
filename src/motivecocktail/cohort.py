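"""Synthetic cohorts: parameter populations and simulated choice data.

The generator emulates the statistical structure the analysis assumes:
cross-participant heterogeneity in the motive parameters (gamma-distributed
nonnegative weights, normal reversal preference, beta lapse rates),
Bernoulli choices driven by the model's per-trial P(yes), and the metadata
the exclusion rules operate on (attention checks, decision times).

The default population is a three-component mixture producing the three
behavioral regimes the analysis is designed to resolve:

* ``justice_warrior`` - high, inequality- and cost-sensitive intervention
  (strong victim-centered aversion with strong action discounting).
* ``pragmatic_helper`` - moderately high, flat, helping-tilted
  intervention (efficiency concern and reversal preference dominate, weak
  choice determinism).
* ``rational_moralist`` - low intervention unless the cost is minimal
  (strong inaction and action discounting at higher cost).

The component hyperparameters are synthetic defaults documented in
``docs/methods.md``; they are not estimates from any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import models as m
from .design import Session, session_frame
from .seeding import substream

#: distribution spec: ("gamma", shape, scale) | ("normal", mu, sd)
#: | ("beta", a, b) | ("point", value)
Dist = Tuple


@dataclass
class PopulationSpec:
    """Mixture population over motive-parameter vectors.

    ``components`` maps a component name to (weight, {param: Dist}).
    Draws are rejection-truncated to the parameter bounds.
    """

    model: str = "cocktail"
    components: Dict[str, Tuple[float, Dict[str, Dist]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("PopulationSpec needs at least one component")
        total = sum(w for w, _ in self.components.values())
        if not np.isfinite(total) or total <= 0:
            raise ValueError("component weights must sum to a positive number")


# Within-component spread: the regime-defining weights (gamma, eta, lambda)
# are kept tight (CV 1/3) so the three behavioral regimes stay distinct;
# the minor weights (alpha, beta, omega) get wide heterogeneity (CV ~0.7),
# matching the order-of-magnitude spread of Fehr-Schmidt inequality-aversion
# weights across people, so each parameter carries real between-participant
# variance for recovery analyses.
_GAMMA_SHAPE = 9.0
_GAMMA_SHAPE_WIDE = 2.0


def _g(mean: float) -> Dist:
    return ("gamma", _GAMMA_SHAPE, mean / _GAMMA_SHAPE)


def _gw(mean: float) -> Dist:
    return ("gamma", _GAMMA_SHAPE_WIDE, mean / _GAMMA_SHAPE_WIDE)


ARCHETYPES: Dict[str, Dict[str, Dist]] = {
    "justice_warrior": {
        "lambda": _g(0.8), "alpha": _gw(0.08), "beta": _gw(0.06),
        "gamma": _g(1.2), "omega": _gw(0.04), "kappa": ("normal", 0.3, 0.25),
        "eta_no": _g(0.5), "eta_yes": _g(8.0),
        "p_min": ("beta", 2.0, 38.0), "p_max": ("beta", 2.0, 38.0),
    },
    "pragmatic_helper": {
        "lambda": _g(0.15), "alpha": _gw(0.15), "beta": _gw(0.4),
        "gamma": _g(0.3), "omega": _g(0.45), "kappa": ("normal", 1.2, 0.3),
        "eta_no": _g(0.3), "eta_yes": _g(10.0),
        "p_min": ("beta", 2.0, 38.0), "p_max": ("beta", 2.0, 38.0),
    },
    "rational_moralist": {
        "lambda": _g(0.6), "alpha": _gw(0.05), "beta": _gw(0.15),
        "gamma": _g(1.2), "omega": _gw(0.03), "kappa": ("normal", 0.1, 0.2),
        "eta_no": _g(5.0), "eta_yes": _g(5.0),
        "p_min": ("beta", 2.0, 38.0), "p_max": ("beta", 2.0, 38.0),
    },
}

#: default mixture weights (three regimes, majority low-intervention)
ARCHETYPE_WEIGHTS: Dict[str, float] = {
    "justice_warrior": 0.35,
    "pragmatic_helper": 0.18,
    "rational_moralist": 0.47,
}

#: baseline-model intervention rates for generating baseline cohorts
BASELINE_Q_DIST: Dist = ("beta", 2.0, 6.0)


def archetype_means(name: str, model: str = "cocktail") -> Dict[str, float]:
    """Mean parameter vector of one archetype component."""
    means = {}
    for p, d in ARCHETYPES[name].items():
        if d[0] == "gamma":
            means[p] = d[1] * d[2]
        elif d[0] == "normal":
            means[p] = d[1]
        elif d[0] == "beta":
            means[p] = d[1] / (d[1] + d[2])
        else:
            means[p] = d[1]
    return {p: means[p] for p in m.MODEL_PARAMS[model] if p in means}


def default_population(model: str = "cocktail") -> PopulationSpec:
    """The documented three-archetype default population."""
    comps = {name: (ARCHETYPE_WEIGHTS[name], dict(dists))
             for name, dists in ARCHETYPES.items()}
    return PopulationSpec(model=model, components=comps)


def _draw_dist(rng: np.random.Generator, dist: Dist,
               bounds: Tuple[float, float]) -> float:
    kind = dist[0]
    lo, hi = bounds
    for _ in range(10_000):
        if kind == "gamma":
            v = rng.gamma(dist[1], dist[2])
        elif kind == "normal":
            v = rng.normal(dist[1], dist[2])
        elif kind == "beta":
            v = rng.beta(dist[1], dist[2])
        elif kind == "point":
            v = dist[1]
            if not (lo <= v <= hi):
                raise ValueError(f"point mass {v} outside bounds {bounds}")
            return float(v)
        else:
            raise ValueError(f"unknown distribution family {kind!r}")
        if lo <= v <= hi:
            return float(v)
    raise ValueError(f"truncation to {bounds} rejected all draws of {dist}")


def draw_population(spec: PopulationSpec, n: int, seed: int
                    ) -> List[Tuple[str, Dict[str, float], str]]:
    """Draw ``n`` (model, parameter vector, component name) triples.

    Parameters for the spec's model are drawn from the component
    distributions and truncated to the model bounds; free parameters not
    covered by the component spec default to 0 (or raise if 0 is outside
    bounds).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(spec.components)
    weights = np.array([spec.components[c][0] for c in names], dtype=float)
    weights = weights / weights.sum()
    free = m.MODEL_PARAMS[spec.model]
    bounds = dict(zip(free, m.param_bounds(spec.model)))
    out = []
    comp_idx = rng.choice(len(names), size=n, p=weights)
    for i in range(n):
        comp = names[comp_idx[i]]
        dists = spec.components[comp][1]
        params: Dict[str, float] = {}
        for p in free:
            if p in dists:
                params[p] = _draw_dist(rng, dists[p], bounds[p])
            else:
                lo, hi = bounds[p]
                if not (lo <= 0.0 <= hi):
                    raise ValueError(f"no distribution for {p} and 0 is "
                                     f"outside its bounds")
                params[p] = 0.0
        out.append((spec.model, params, comp))
    return out


def population_for_model(model: str) -> PopulationSpec:
    """Default generating population for any model in the family.

    Sub-models reuse the archetype mixture restricted to their own free
    parameters; the baseline model draws its rate q from a beta law; the
    simple-response model uses documented synthetic weight distributions.
    """
    if model == "baseline":
        return PopulationSpec(model="baseline",
                              components={"all": (1.0, {"q": BASELINE_Q_DIST})})
    if model == "simple_response":
        dists: Dict[str, Dist] = {
            "temperature": _g(1.0),
            "b_scenario": ("normal", 0.5, 0.5),
            "b_inequality": ("normal", -0.8, 0.4),
            "b_cost": ("normal", 0.8, 0.4),
            "b_ratio": ("normal", -0.4, 0.3),
            "p_min": ("beta", 2.0, 18.0),
            "p_max": ("beta", 2.0, 18.0),
        }
        return PopulationSpec(model="simple_response",
                              components={"all": (1.0, dists)})
    spec = default_population(model="cocktail")
    free = set(m.MODEL_PARAMS[model])
    comps = {
        name: (w, {p: d for p, d in dists.items() if p in free})
        for name, (w, dists) in spec.components.items()
    }
    return PopulationSpec(model=model, components=comps)


# --------------------------------------------------------------------------
# Choice simulation


@dataclass
class ParticipantDataset:
    """Trials plus choices (and synthetic-truth metadata) for one person."""

    participant_id: str
    trials: pd.DataFrame  # session schema + choice column
    true_model: Optional[str] = None
    true_params: Optional[Dict[str, float]] = None
    archetype: Optional[str] = None
    attention_correct: Optional[int] = None
    attention_total: int = 12

    @property
    def choices(self) -> np.ndarray:
        return self.trials["choice"].to_numpy(dtype=int)

    @property
    def attention_accuracy(self) -> Optional[float]:
        if self.attention_correct is None:
            return None
        return self.attention_correct / self.attention_total

    @property
    def mean_decision_time(self) -> Optional[float]:
        if "decision_time" not in self.trials:
            return None
        return float(self.trials["decision_time"].mean())


def simulate_dataset(model: str, params: Mapping[str, float],
                     session: "Session | pd.DataFrame", seed: int,
                     participant_id: str = "p0",
                     with_decision_times: bool = False,
                     attention_accuracy: Optional[float] = None
                     ) -> ParticipantDataset:
    """Simulate one participant: choice ~ Bernoulli(P(yes)) per trial.

    Optionally attaches synthetic decision times (lognormal, slower near
    P(yes) = 0.5, mimicking the inverted-U difficulty pattern; used only to
    exercise exclusion rules) and attention-check outcomes
    (Binomial(12, accuracy)).
    """
    m.validate_params(model, params)
    trials = session.to_frame(participant_id) if isinstance(session, Session) \
        else session.copy()
    trials["participant_id"] = participant_id
    rng = np.random.default_rng(seed)
    p = m.choice_probability(model, params, m.trial_features(trials))
    trials["choice"] = (rng.random(len(trials)) < p).astype(int)
    attention = None
    if with_decision_times:
        mean_dt = 0.6 + 1.2 * (1.0 - 2.0 * np.abs(p - 0.5))  # inverted U
        trials["decision_time"] = rng.lognormal(np.log(mean_dt), 0.35)
    if attention_accuracy is not None:
        attention = int(rng.binomial(12, attention_accuracy))
    return ParticipantDataset(
        participant_id=participant_id, trials=trials, true_model=model,
        true_params=dict(params), attention_correct=attention,
    )


def simulate_cohort(population: PopulationSpec, n: int, seed: int,
                    session_seed: Optional[int] = None,
                    shared_session: bool = False,
                    with_decision_times: bool = False,
                    attention_accuracy: Optional[Sequence[float]] = None
                    ) -> List[ParticipantDataset]:
    """Draw a population and simulate one dataset per participant.

    Each participant gets an independent session randomization (or a
    shared one when ``shared_session``); all randomness derives from
    ``seed`` through named substreams.
    """
    draws = draw_population(population, n, substream(seed, "pop"))
    datasets = []
    for i, (model, params, comp) in enumerate(draws):
        s_seed = session_seed if shared_session and session_seed is not None \
            else substream(seed, "session", i)
        trials = session_frame(s_seed, participant_id=f"p{i:03d}")
        acc = attention_accuracy[i] if attention_accuracy is not None else None
        ds = simulate_dataset(model, params, trials,
                              seed=substream(seed, "choice", i),
                              participant_id=f"p{i:03d}",
                              with_decision_times=with_decision_times,
                              attention_accuracy=acc)
        ds.archetype = comp
        datasets.append(ds)
    return datasets


# --------------------------------------------------------------------------
# Exclusions


@dataclass
class ExclusionRules:
    """Participant-level exclusion thresholds."""

    attention_min_accuracy: Optional[float] = 0.75  # strictly below excludes
    decision_time_sd: Optional[float] = 2.5  # mean DT above cohort mean + z*sd


def apply_exclusions(datasets: Sequence[ParticipantDataset],
                     rules: ExclusionRules = ExclusionRules()
                     ) -> Tuple[List[ParticipantDataset], pd.DataFrame]:
    """Apply attention and decision-time exclusions.

    Attention: excluded iff accuracy is strictly below the threshold.
    Decision time: excluded iff the participant's mean decision time
    exceeds cohort mean + ``decision_time_sd`` standard deviations (of the
    per-participant means).  Returns (retained, report).
    """
    rows = []
    excluded = set()
    if rules.attention_min_accuracy is not None:
        for ds in datasets:
            acc = ds.attention_accuracy
            if acc is None:
                raise ValueError(f"{ds.participant_id}: attention rule "
                                 "enabled but no attention data")
            if acc < rules.attention_min_accuracy:
                excluded.add(ds.participant_id)
                rows.append({"participant_id": ds.participant_id,
                             "rule": "attention", "value": acc,
                             "threshold": rules.attention_min_accuracy})
    if rules.decision_time_sd is not None:
        means = []
        for ds in datasets:
            mdt = ds.mean_decision_time
            if mdt is None:
                raise ValueError(f"{ds.participant_id}: decision-time rule "
                                 "enabled but no decision_time column")
            means.append(mdt)
        arr = np.asarray(means)
        cutoff = arr.mean() + rules.decision_time_sd * arr.std(ddof=0)
        for ds, mdt in zip(datasets, means):
            if mdt > cutoff:
                excluded.add(ds.participant_id)
                rows.append({"participant_id": ds.participant_id,
                             "rule": "decision_time", "value": mdt,
                             "threshold": cutoff})
    retained = [ds for ds in datasets if ds.participant_id not in excluded]
    report = pd.DataFrame(rows, columns=["participant_id", "rule", "value",
                                         "threshold"])
    return retained, report
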