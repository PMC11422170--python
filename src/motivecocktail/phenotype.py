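"""Behavioral phenotyping: condition profiles, clustering, sensitivities.

Participants are summarized by their intervention probability in each of
the 100 factorial conditions (mean over the 3 repetitions, nominal-split
bins), clustered by Euclidean k-means with silhouette-selected k, and
characterized by normalized intervention-probability differences after
dichotomizing each manipulated variable:

* inequality: high = {90:10, 80:20, 70:30}, low = {60:40, 50:50}
* cost: low <= 20, high > 20
* ratio: high = 3.0, low = 1.5
* scenario: helping vs punishment

Each sensitivity is (P(high side) - P(low side)) / overall P(yes), signed
as listed (helping minus punishment, high ratio minus low, low cost minus
high, high inequality minus low).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import ParticipantDataset
from .design import enumerate_conditions
from .estimators import ArchetypeKMeans

CONDITION_COLUMNS = ("scenario", "split", "cost", "ratio")

HIGH_INEQUALITY_SPLITS = (70, 80, 90)
LOW_INEQUALITY_SPLITS = (50, 60)
LOW_COST_MAX = 20


@dataclass
class ClusterReport:
    """Outcome of silhouette-selected k-means on condition profiles."""

    k: int
    assignments: pd.Series
    centroids: np.ndarray
    silhouette_by_k: Dict[int, float]
    archetype_names: List[str]


def _condition_key(c) -> Tuple:
    return (c.scenario, c.nominal_split, c.cost, c.ratio)


def condition_profiles(datasets: Sequence[ParticipantDataset]) -> pd.DataFrame:
    """Participants x 100 mean-intervention matrix.

    Columns follow the deterministic ``enumerate_conditions`` order;
    raises if a participant does not cover all 100 conditions.
    """
    order = [_condition_key(c) for c in enumerate_conditions()]
    rows = {}
    for ds in datasets:
        grp = ds.trials.groupby(list(CONDITION_COLUMNS))["choice"].mean()
        missing = [k for k in order if k not in grp.index]
        if missing:
            raise ValueError(
                f"{ds.participant_id}: missing conditions {missing[:5]}"
                + ("..." if len(missing) > 5 else ""))
        rows[ds.participant_id] = [grp[k] for k in order]
    cols = [f"{s[:3]}_{sp}_{c}_{r}" for s, sp, c, r in order]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _profile_sensitivities(profile: np.ndarray) -> Dict[str, float]:
    """Dichotomized sensitivities of one 100-condition profile row."""
    conds = enumerate_conditions()
    p = np.asarray(profile, dtype=float)
    overall = p.mean()
    out = {"overall": float(overall)}
    masks = {
        "scenario": (np.array([c.scenario == "helping" for c in conds]),
                     np.array([c.scenario == "punishment" for c in conds])),
        "inequality": (np.array([c.nominal_split in HIGH_INEQUALITY_SPLITS
                                 for c in conds]),
                       np.array([c.nominal_split in LOW_INEQUALITY_SPLITS
                                 for c in conds])),
        "cost": (np.array([c.cost <= LOW_COST_MAX for c in conds]),
                 np.array([c.cost > LOW_COST_MAX for c in conds])),
        "ratio": (np.array([c.ratio == 3.0 for c in conds]),
                  np.array([c.ratio == 1.5 for c in conds])),
    }
    if overall == 0:
        for name in masks:
            out[name] = float("nan")
        out["defined"] = False
        return out
    for name, (hi, lo) in masks.items():
        out[name] = float((p[hi].mean() - p[lo].mean()) / overall)
    # pairwise difference-of-differences, same normalization
    names = list(masks)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            hi_i, lo_i = masks[names[i]]
            hi_j, lo_j = masks[names[j]]
            dd = ((p[hi_i & hi_j].mean() - p[hi_i & lo_j].mean())
                  - (p[lo_i & hi_j].mean() - p[lo_i & lo_j].mean()))
            out[f"{names[i]}_x_{names[j]}"] = float(dd / overall)
    out["defined"] = True
    return out


def sensitivity_profile(dataset: ParticipantDataset) -> Dict[str, float]:
    """Normalized P(yes) differences for one participant's choices."""
    profile = condition_profiles([dataset]).iloc[0].to_numpy()
    return _profile_sensitivities(profile)


def name_archetype(centroid: np.ndarray) -> str:
    """Deterministic diagnostic label for a cluster centroid.

    Reporting plumbing on top of the clustering: thresholds on the
    centroid's overall level and dichotomized sensitivities map it to one
    of six descriptive labels.
    """
    s = _profile_sensitivities(centroid)
    overall = s["overall"]
    if overall < 0.02:
        return "random_response"
    if overall >= 0.35:
        if s["scenario"] > 0.5 and abs(s["inequality"]) < 0.5:
            return "pragmatic_helper"
        if s["inequality"] >= 0.3:
            return "justice_warrior"
        if abs(s["scenario"]) > 0.5:
            return "scenario_response"
        return "pragmatic_helper"
    if s["cost"] >= 0.5 and s["inequality"] >= 0.2:
        return "rational_moralist"
    if s["cost"] >= 0.5:
        return "cost_response"
    if abs(s["scenario"]) > 0.5:
        return "scenario_response"
    return "rational_moralist"


def select_and_cluster(profiles: pd.DataFrame,
                       k_range: Sequence[int] = tuple(range(2, 11)),
                       n_restarts: int = 100,
                       seed: Optional[int] = 0) -> ClusterReport:
    """Silhouette-selected k-means over condition profiles."""
    est = ArchetypeKMeans(k_range=k_range, n_restarts=n_restarts,
                          random_state=seed)
    est.fit(profiles.to_numpy(dtype=float))
    assignments = pd.Series(est.labels_, index=profiles.index, name="cluster")
    names = [name_archetype(c) for c in est.cluster_centers_]
    return ClusterReport(k=est.k_, assignments=assignments,
                         centroids=est.cluster_centers_,
                         silhouette_by_k=est.silhouette_by_k_,
                         archetype_names=names)
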