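"""Maximum-likelihood fitting of the model family (thin wrappers over
:class:`~motivecocktail.estimators.ChoiceModel`)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import models as m
from .cohort import ParticipantDataset
from .estimators import ChoiceModel, _nll_from_probs
from .seeding import substream


@dataclass
class FitOptions:
    """Multistart-MLE settings (reference procedure: 500 starts)."""

    n_starts: int = 500
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    """One participant x model fit."""

    participant_id: str
    model: str
    params: Dict[str, float]
    nll: float
    k: int
    n: int
    aicc: float
    n_starts_used: int
    best_start_index: int
    at_bounds: Dict[str, bool] = field(default_factory=dict)
    error: Optional[str] = None


def aicc(nll: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: 2*nll + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined for n <= k + 1")
    return 2.0 * nll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def negative_log_likelihood(model: str, params: Mapping[str, float],
                            dataset: ParticipantDataset) -> float:
    """Bernoulli NLL (nats) of the dataset's choices under the model.

    Probabilities are clipped to [1e-12, 1 - 1e-12] before the logs.
    """
    if len(dataset.trials) == 0:
        raise ValueError("empty dataset")
    m.validate_params(model, params)
    p = m.choice_probability(model, params, m.trial_features(dataset.trials))
    return _nll_from_probs(p, dataset.choices.astype(float))


def fit_model(model: str, dataset: ParticipantDataset,
              options: FitOptions = FitOptions()) -> FitResult:
    """Fit one model to one participant by multistart bounded MLE."""
    est = ChoiceModel(model=model, n_starts=options.n_starts,
                      tol=options.tol, random_state=options.seed)
    est.fit(dataset.trials, dataset.choices)
    return FitResult(
        participant_id=dataset.participant_id, model=model,
        params=est.params_, nll=est.nll_, k=est.k_, n=est.n_,
        aicc=est.aicc_, n_starts_used=est.n_starts_used_,
        best_start_index=est.best_start_index_, at_bounds=est.at_bounds_,
    )


def fit_cohort(models: Sequence[str], datasets: Sequence[ParticipantDataset],
               options: FitOptions = FitOptions()) -> pd.DataFrame:
    """Fit every model to every participant.

    Per-fit seeds are derived deterministically from ``options.seed`` and
    the (participant id, model) pair, so results do not depend on
    execution order.  Failed fits are recorded in the ``error`` column
    without aborting the grid.

    Returns a tidy table with one row per participant x model, including
    the parameter estimates as ``param_<name>`` columns.
    """
    if not models or not datasets:
        raise ValueError("models and datasets must be non-empty")
    rows = []
    for ds in datasets:
        for model in models:
            opts = FitOptions(n_starts=options.n_starts, tol=options.tol,
                              seed=substream(options.seed, ds.participant_id, model))
            try:
                fr = fit_model(model, ds, opts)
            except Exception as exc:  # recorded, grid continues
                warnings.warn(f"fit failed for {ds.participant_id}/{model}: {exc}",
                              stacklevel=2)
                rows.append({"participant_id": ds.participant_id,
                             "model": model, "nll": np.nan, "k": np.nan,
                             "n": np.nan, "aicc": np.nan, "error": str(exc)})
                continue
            row = {"participant_id": fr.participant_id, "model": fr.model,
                   "nll": fr.nll, "k": fr.k, "n": fr.n, "aicc": fr.aicc,
                   "error": None}
            for p, v in fr.params.items():
                row[f"param_{p}"] = v
            rows.append(row)
    return pd.DataFrame(rows)
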