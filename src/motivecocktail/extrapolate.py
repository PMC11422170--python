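"""Out-of-sample use of the motive utilities.

Two tools: utility-gain phase diagrams (delta-U = U_yes - U_no over
inequality x cost, one panel per scenario x ratio) and simulation of
continuous expenditure protocols from other intervention paradigms, where
an intervener chooses among candidate costs (0 = no intervention) and the
predicted expenditure is the utility-maximizing cost.

Second-party intervention (the victim punishing on their own behalf) is
modeled by substituting the victim's payoff x2 for the intervener's
endowment in the utility terms and dropping the efficiency concern
(omega = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import models as m
from .design import COSTS, RATIOS, SCENARIOS, SPLITS


@dataclass
class GridSpec:
    """Axes of a delta-U phase diagram."""

    splits: Sequence[int] = SPLITS
    costs: Sequence[float] = COSTS
    scenarios: Sequence[str] = SCENARIOS
    ratios: Sequence[float] = RATIOS
    x3: float = 50.0


@dataclass
class DeltaUGrid:
    """delta-U panels keyed by (scenario, ratio); rows = costs, cols = splits."""

    panels: Dict[Tuple[str, float], np.ndarray]
    splits: Sequence[int]
    costs: Sequence[float]
    scaled: bool = False


def delta_u_grid(params: Mapping[str, float], gridspec: GridSpec = GridSpec(),
                 model: str = "cocktail", scale: bool = False) -> DeltaUGrid:
    """delta-U = U_yes - U_no per (inequality, cost) cell and panel.

    With ``scale=True``, each column of each panel is scaled separately
    for positive and negative values: positives divided by the column's
    positive maximum, negatives by the magnitude of the column's minimum,
    mapping the panel into [-1, 1].
    """
    if not gridspec.splits or not gridspec.costs:
        raise ValueError("empty grid")
    panels = {}
    for scen in gridspec.scenarios:
        for ratio in gridspec.ratios:
            rows = []
            for cost in gridspec.costs:
                trials = pd.DataFrame({
                    "scenario": scen,
                    "x1": list(gridspec.splits),
                    "x2": [100 - s for s in gridspec.splits],
                    "x3": gridspec.x3,
                    "cost": float(cost),
                    "ratio": float(ratio),
                })
                rows.append(m.utility_pair(model, params, trials).delta_u)
            grid = np.vstack(rows)
            if scale:
                grid = _scale_signed_columns(grid)
            panels[(scen, ratio)] = grid
    return DeltaUGrid(panels=panels, splits=list(gridspec.splits),
                      costs=list(gridspec.costs), scaled=scale)


def _scale_signed_columns(grid: np.ndarray) -> np.ndarray:
    out = grid.astype(float).copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        pos = col > 0
        neg = col < 0
        if pos.any():
            col[pos] = col[pos] / col[pos].max()
        if neg.any():
            col[neg] = col[neg] / abs(col[neg].min())
        out[:, j] = col
    return out


@dataclass
class ExpenditureProtocol:
    """A continuous-expenditure intervention protocol.

    ``transfer_levels`` are the receiver's share of the 100-token pie
    (x2 = transfer, x1 = 100 - transfer).  ``candidate_costs`` includes 0
    (no intervention); the impact on the target is ``impact_ratio *
    cost``.  ``intervener_role`` selects who pays: the unaffected third
    party (endowment ``endowment``) or the second party / victim (whose
    endowment is their payoff x2).  ``efficiency_concern_off`` forces
    omega = 0, as assumed for second parties and for norm-violation
    (theft) settings.
    """

    intervener_role: str = "third_party"  # or "second_party"
    scenario: str = "punishment"
    candidate_costs: Sequence[float] = tuple(range(0, 101, 10))
    impact_ratio: float = 3.0
    transfer_levels: Sequence[float] = tuple(range(0, 101, 10))
    endowment: float = 50.0
    efficiency_concern_off: bool = False

    def __post_init__(self) -> None:
        if self.intervener_role not in ("third_party", "second_party"):
            raise ValueError("intervener_role must be third_party or second_party")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        costs = list(self.candidate_costs)
        if any(c < 0 for c in costs) or costs != sorted(costs):
            raise ValueError("candidate_costs must be nonnegative and sorted")
        if self.impact_ratio <= 0:
            raise ValueError("impact_ratio must be positive")


def simulate_expenditure(params: Mapping[str, float],
                         protocol: ExpenditureProtocol,
                         model: str = "cocktail",
                         rule: str = "argmax") -> pd.DataFrame:
    """Predicted expenditure per transfer level.

    For each transfer level the utility of every candidate cost is
    evaluated (cost 0 = not intervening) and the expenditure is the
    utility-maximizing cost (``rule='argmax'``, ties toward the smaller
    cost) or the softmax-weighted expected cost (``rule='softmax'``,
    using the model's inverse temperature).  Deterministic: a pure
    function of (params, protocol).
    """
    if rule not in ("argmax", "softmax"):
        raise ValueError("rule must be 'argmax' or 'softmax'")
    params = dict(params)
    if protocol.efficiency_concern_off or protocol.intervener_role == "second_party":
        params["omega"] = 0.0
    rows = []
    for transfer in protocol.transfer_levels:
        x1 = 100.0 - transfer
        x2 = float(transfer)
        endow = x2 if protocol.intervener_role == "second_party" \
            else protocol.endowment
        utils = []
        for cost in protocol.candidate_costs:
            trials = pd.DataFrame({
                "scenario": [protocol.scenario], "x1": [x1], "x2": [x2],
                "x3": [endow], "cost": [float(cost)],
                "ratio": [protocol.impact_ratio],
            })
            ub = m.utility_pair(model, params, trials)
            # cost 0 is "no intervention": its utility is U_no
            utils.append(float(ub.u_no[0]) if cost == 0 else float(ub.u_yes[0]))
        utils = np.asarray(utils)
        costs = np.asarray(protocol.candidate_costs, dtype=float)
        if rule == "argmax":
            spend = costs[int(np.argmax(utils))]  # first max = smaller cost
        else:
            lam = params.get("lambda", 1.0)
            w = np.exp(np.clip(lam * (utils - utils.max()), -700, 0))
            spend = float((w * costs).sum() / w.sum())
        rows.append({"transfer": transfer, "expenditure": float(spend),
                     "max_utility": float(utils.max())})
    return pd.DataFrame(rows)
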