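"""Factorial design of the intervene-or-watch task.

The task presents a third party (endowed with 50 tokens) with the outcome of
a dictator game between a "transgressor" and a "victim", plus a costly
intervention offer: pay ``cost`` tokens to reduce the transgressor's payoff
(punishment scenario) or increase the victim's payoff (helping scenario) by
``ratio * cost`` tokens.  Four variables are crossed factorially:

* scenario: punishment / helping (varied between blocks)
* nominal transgressor:victim split of 100 tokens: 50:50 ... 90:10
* intervention cost: 10 ... 50 tokens
* impact-to-cost ratio: 1.5 or 3.0

yielding 100 unique conditions; a session repeats each condition three times
(300 trials) across six scenario-homogeneous blocks of 50 trials.  The
displayed split is jittered by up to +/-2 tokens around the nominal split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

SCENARIOS: Tuple[str, str] = ("punishment", "helping")
SPLITS: Tuple[int, ...] = (50, 60, 70, 80, 90)
COSTS: Tuple[int, ...] = (10, 20, 30, 40, 50)
RATIOS: Tuple[float, float] = (1.5, 3.0)
THIRD_PARTY_ENDOWMENT: int = 50
N_CONDITIONS: int = len(SCENARIOS) * len(SPLITS) * len(COSTS) * len(RATIOS)
N_REPETITIONS: int = 3
N_BLOCKS: int = 6
TRIALS_PER_BLOCK: int = 50
JITTER_RULES: Tuple[str, ...] = ("uniform_int", "none")


@dataclass(frozen=True, order=True)
class Condition:
    """One cell of the factorial crossing."""

    scenario: str
    nominal_split: int  # transgressor share of the 100 tokens
    cost: int
    ratio: float

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.nominal_split not in SPLITS:
            raise ValueError(f"nominal_split must be one of {SPLITS}")
        if self.cost not in COSTS:
            raise ValueError(f"cost must be one of {COSTS}")
        if self.ratio not in RATIOS:
            raise ValueError(f"ratio must be one of {RATIOS}")

    @property
    def victim_share(self) -> int:
        return 100 - self.nominal_split


@dataclass(frozen=True)
class Trial:
    """A single decision context with the (possibly jittered) payoffs."""

    condition: Condition
    x1: int  # transgressor pre-intervention payoff
    x2: int  # victim pre-intervention payoff
    x3: int  # third-party endowment
    block_index: int  # 1..6
    repetition_index: int  # 1..3

    def __post_init__(self) -> None:
        if self.x1 + self.x2 != 100:
            raise ValueError("x1 + x2 must equal 100")
        if abs(self.x1 - self.condition.nominal_split) > 2:
            raise ValueError("jitter exceeds +/-2 tokens")
        if self.x3 != THIRD_PARTY_ENDOWMENT:
            raise ValueError(f"x3 must be {THIRD_PARTY_ENDOWMENT}")


@dataclass
class Session:
    """An ordered 300-trial realization of the design for one participant."""

    trials: List[Trial]
    seed: int
    block_layout: Dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self, participant_id: str = "p0") -> pd.DataFrame:
        """Tidy one-row-per-trial table (the export schema)."""
        rows = []
        for i, t in enumerate(self.trials):
            rows.append(
                {
                    "participant_id": participant_id,
                    "trial_index": i,
                    "block": t.block_index,
                    "scenario": t.condition.scenario,
                    "split": t.condition.nominal_split,
                    "x1": t.x1,
                    "x2": t.x2,
                    "x3": t.x3,
                    "cost": t.condition.cost,
                    "ratio": t.condition.ratio,
                }
            )
        return pd.DataFrame(rows)


def enumerate_conditions() -> List[Condition]:
    """All 100 cells of the 2 x 5 x 5 x 2 crossing, sorted deterministically.

    Sort order is (scenario, split, cost, ratio) with scenarios in the
    declared (punishment, helping) order.
    """
    out = [
        Condition(scenario=s, nominal_split=sp, cost=c, ratio=r)
        for s in SCENARIOS
        for sp in SPLITS
        for c in COSTS
        for r in RATIOS
    ]
    return out


def _draw_jitter(rng: np.random.Generator, rule: str) -> int:
    if rule == "uniform_int":
        return int(rng.integers(-2, 3))
    if rule == "none":
        return 0
    raise ValueError(f"unknown jitter_rule {rule!r}; choose from {JITTER_RULES}")


def generate_session(seed: int, jitter_rule: str = "uniform_int") -> Session:
    """Generate one randomized 300-trial session.

    Scenario alternates between blocks (starting scenario decided by the
    seed); each scenario's 50 conditions appear exactly once in each of its
    three blocks, shuffled within block.  The transgressor share is jittered
    by an integer drawn uniformly from {-2,...,+2} (``jitter_rule
    ='uniform_int'``), keeping x1 + x2 = 100.

    Same seed, same rule -> identical session.
    """
    if jitter_rule not in JITTER_RULES:
        raise ValueError(f"unknown jitter_rule {jitter_rule!r}; choose from {JITTER_RULES}")
    rng = np.random.default_rng(seed)
    first = SCENARIOS[int(rng.integers(0, 2))]
    order = [first, SCENARIOS[1 - SCENARIOS.index(first)]]
    block_layout = {b + 1: order[b % 2] for b in range(N_BLOCKS)}

    by_scenario = {
        s: [c for c in enumerate_conditions() if c.scenario == s] for s in SCENARIOS
    }
    rep_counter = {s: 0 for s in SCENARIOS}
    trials: List[Trial] = []
    for b in range(1, N_BLOCKS + 1):
        scen = block_layout[b]
        rep_counter[scen] += 1
        conds = list(by_scenario[scen])
        rng.shuffle(conds)
        for cond in conds:
            x1 = cond.nominal_split + _draw_jitter(rng, jitter_rule)
            trials.append(
                Trial(
                    condition=cond,
                    x1=x1,
                    x2=100 - x1,
                    x3=THIRD_PARTY_ENDOWMENT,
                    block_index=b,
                    repetition_index=rep_counter[scen],
                )
            )
    return Session(trials=trials, seed=seed, block_layout=block_layout)


def session_frame(seed: int, jitter_rule: str = "uniform_int",
                  participant_id: str = "p0") -> pd.DataFrame:
    """Convenience: generate a session directly as a tidy trial table."""
    return generate_session(seed, jitter_rule).to_frame(participant_id)


def replicate_trials(trials: pd.DataFrame, multiplier: int) -> pd.DataFrame:
    """Tile a trial table ``multiplier`` times (used for data-rich recovery
    runs, e.g. 10 x 300 = 3,000 trials)."""
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    out = pd.concat([trials] * multiplier, ignore_index=True)
    out["trial_index"] = np.arange(len(out))
    return out
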