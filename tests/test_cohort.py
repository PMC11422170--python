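"""Synthetic-cohort generator: populations, simulation, exclusions."""

import numpy as np
import pandas as pd
import pytest

import motivecocktail as mc
from motivecocktail.cohort import ExclusionRules, PopulationSpec
from motivecocktail.models import MODEL_PARAMS, param_bounds


class TestDrawPopulation:
    def test_point_mass_population_is_degenerate(self):
        dists = {p: ("point", 0.5) if p != "kappa" else ("point", 0.0)
                 for p in MODEL_PARAMS["SI_SCI"]}
        spec = PopulationSpec(model="SI_SCI", components={"all": (1.0, dists)})
        draws = mc.draw_population(spec, 5, seed=0)
        assert all(params == draws[0][1] for _, params, _ in draws)

    def test_draws_respect_bounds(self):
        draws = mc.draw_population(mc.default_population(), 200, seed=1)
        bounds = dict(zip(MODEL_PARAMS["cocktail"], param_bounds("cocktail")))
        for _, params, _ in draws:
            for p, v in params.items():
                lo, hi = bounds[p]
                assert lo <= v <= hi

    def test_gamma_moment_matches(self):
        # lambda ~ gamma(shape=2, scale=0.5): mean 1.0
        dists = {"lambda": ("gamma", 2.0, 0.5)}
        spec = PopulationSpec(model="SI", components={"all": (1.0, dists)})
        vals = np.array([d[1]["lambda"] for d in mc.draw_population(spec, 10_000, seed=2)])
        se = np.sqrt(2 * 0.5 ** 2 / 10_000)
        assert abs(vals.mean() - 1.0) < 3 * se

    def test_impossible_truncation_raises(self):
        spec = PopulationSpec(model="SI",
                              components={"all": (1.0, {"lambda": ("normal", 50.0, 0.01)})})
        with pytest.raises(ValueError, match="truncation|bounds"):
            mc.draw_population(spec, 1, seed=0)

    def test_seeded_reproducibility(self):
        a = mc.draw_population(mc.default_population(), 10, seed=7)
        b = mc.draw_population(mc.default_population(), 10, seed=7)
        assert a == b


class TestSimulateDataset:
    def test_degenerate_bernoulli_all_yes(self, session_trials):
        ds = mc.simulate_dataset("baseline", {"q": 1.0}, session_trials, seed=0)
        assert ds.choices.sum() == 300

    def test_yes_fraction_within_binomial_band(self, session_trials):
        from scipy.stats import binom
        ds = mc.simulate_dataset("baseline", {"q": 0.25}, session_trials, seed=3)
        lo, hi = binom.ppf([0.005, 0.995], 300, 0.25)
        assert lo <= ds.choices.sum() <= hi

    def test_determinism(self, session_trials, cocktail_params):
        a = mc.simulate_dataset("cocktail", cocktail_params, session_trials, seed=5)
        b = mc.simulate_dataset("cocktail", cocktail_params, session_trials, seed=5)
        assert a.trials.equals(b.trials)

    def test_long_run_calibration(self, cocktail_params):
        """Empirical per-condition yes rates converge to P(yes)."""
        trials = mc.session_frame(0)
        big = mc.design.replicate_trials(trials, 30)
        ds = mc.simulate_dataset("cocktail", cocktail_params, big, seed=9)
        p = mc.choice_probability("cocktail", cocktail_params, big)
        emp = ds.trials.assign(p=p).groupby(["scenario", "split", "cost", "ratio"])
        agg = emp.agg(rate=("choice", "mean"), prob=("p", "mean"), n=("choice", "size"))
        # 99.9% binomial band per condition
        z = 3.29
        band = z * np.sqrt(agg["prob"] * (1 - agg["prob"]) / agg["n"]) + 1e-9
        assert (np.abs(agg["rate"] - agg["prob"]) <= band).mean() > 0.98


class TestExclusions:
    def _mk(self, pid, acc=None, dt=None, n=4):
        trials = pd.DataFrame({"scenario": ["punishment", "helping"] * (n // 2),
                               "x1": 70, "x2": 30, "x3": 50, "cost": 10,
                               "ratio": 1.5, "choice": 0})
        if dt is not None:
            trials["decision_time"] = dt
        att = None if acc is None else int(round(acc * 12))
        return mc.ParticipantDataset(participant_id=pid, trials=trials,
                                     attention_correct=att)

    def test_attention_rule_is_strict_below(self):
        cohort = [self._mk("a", acc=8 / 12), self._mk("b", acc=9 / 12),
                  self._mk("c", acc=1.0)]
        kept, report = mc.apply_exclusions(
            cohort, ExclusionRules(attention_min_accuracy=0.75,
                                   decision_time_sd=None))
        assert [d.participant_id for d in kept] == ["b", "c"]  # 9/12 = 75% retained
        assert report["participant_id"].tolist() == ["a"]
        assert report["rule"].tolist() == ["attention"]

    def test_identical_decision_times_exclude_nobody(self):
        cohort = [self._mk(f"p{i}", dt=1.0) for i in range(5)]
        kept, report = mc.apply_exclusions(
            cohort, ExclusionRules(attention_min_accuracy=None,
                                   decision_time_sd=2.5))
        assert len(kept) == 5 and report.empty

    def test_slow_outlier_excluded_and_idempotent(self):
        cohort = [self._mk(f"p{i}", dt=1.0) for i in range(10)]
        cohort.append(self._mk("slow", dt=50.0))
        rules = ExclusionRules(attention_min_accuracy=None, decision_time_sd=2.5)
        kept, report = mc.apply_exclusions(cohort, rules)
        assert "slow" not in [d.participant_id for d in kept]
        kept2, report2 = mc.apply_exclusions(kept, rules)
        assert [d.participant_id for d in kept2] == [d.participant_id for d in kept]

    def test_missing_fields_raise(self):
        with pytest.raises(ValueError, match="attention"):
            mc.apply_exclusions([self._mk("a")],
                                ExclusionRules(attention_min_accuracy=0.75,
                                               decision_time_sd=None))


def test_simulated_decision_times_and_attention(session_trials, cocktail_params):
    ds = mc.simulate_dataset("cocktail", cocktail_params, session_trials,
                             seed=1, with_decision_times=True,
                             attention_accuracy=0.9)
    assert "decision_time" in ds.trials
    assert (ds.trials["decision_time"] > 0).all()
    assert 0 <= ds.attention_correct <= 12
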