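"""Model comparison: per-participant delta-AICc and group-level
random-effects Bayesian model selection (RFX-BMS).

RFX-BMS treats the model identity of each participant as a random effect
drawn from a population frequency vector r ~ Dirichlet(alpha).  A
variational update yields the posterior over r; the exceedance probability
(EP) of model k is P(r_k > r_j for all j), and the protected exceedance
probability (PEP) shrinks EP toward uniform by the Bayesian omnibus risk
(BOR), the posterior probability that all models are equally frequent:

    PEP_k = EP_k * (1 - BOR) + BOR / K.

The per-participant log model evidence is approximated by -AICc/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc, digamma, gammaln, logsumexp


@dataclass
class BMSResult:
    """Posterior summary of random-effects Bayesian model selection."""

    models: Sequence[str]
    alpha_post: np.ndarray
    expected_freq: np.ndarray
    ep: np.ndarray
    bor: float
    pep: np.ndarray
    n_iter: int

    def to_dict(self) -> Dict[str, object]:
        return {
            "models": list(self.models),
            "alpha_post": self.alpha_post.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "ep": self.ep.tolist(),
            "bor": float(self.bor),
            "pep": self.pep.tolist(),
            "n_iter": self.n_iter,
        }


def delta_aicc(fit_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant AICc minus the participant's lowest AICc.

    Adds a ``best`` flag: the row-minimum model, ties broken toward the
    model with fewer free parameters.  Raises if any participant x model
    cell is missing or failed.
    """
    tab = fit_table.copy()
    bad = tab[tab["aicc"].isna()]
    if len(bad):
        cells = [f"{r.participant_id}/{r.model}" for r in bad.itertuples()]
        raise ValueError(f"missing or failed fits for cells: {cells}")
    participants = tab["participant_id"].unique()
    models = tab["model"].unique()
    counts = tab.groupby("participant_id")["model"].nunique()
    if (counts != len(models)).any():
        missing = counts[counts != len(models)].index.tolist()
        raise ValueError(f"incomplete model grid for participants {missing}")
    tab["delta_aicc"] = tab["aicc"] - tab.groupby("participant_id")["aicc"].transform("min")
    best_flags = np.zeros(len(tab), dtype=bool)
    for pid, grp in tab.groupby("participant_id"):
        # argmin AICc; ties toward fewer parameters
        cand = grp.sort_values(["aicc", "k"], kind="stable")
        best_flags[cand.index[0]] = True
    tab["best"] = best_flags
    return tab


def best_model_counts(delta_table: pd.DataFrame) -> pd.Series:
    """How many participants each model fits best (from delta_aicc output)."""
    winners = delta_table[delta_table["best"]]
    return winners.groupby("model").size().reindex(
        delta_table["model"].unique(), fill_value=0)


def evidence_matrix(fit_table: pd.DataFrame) -> pd.DataFrame:
    """Participants x models log-evidence proxies (-AICc/2, nats)."""
    piv = fit_table.pivot(index="participant_id", columns="model",
                          values="aicc")
    if piv.isna().any().any():
        raise ValueError("evidence matrix has missing cells")
    return -piv / 2.0


def _free_energy_rfx(lme: np.ndarray, alpha: np.ndarray,
                     g: np.ndarray, alpha0: np.ndarray) -> float:
    """Variational free energy of the random-effects model."""
    a_sum = alpha.sum()
    elog_r = digamma(alpha) - digamma(a_sum)
    f = float((g * (lme + elog_r)).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_z = -(g * np.where(g > 0, np.log(g), 0.0)).sum()
    f += float(ent_z)
    # E[log p(r)] - E[log q(r)]
    f += float(gammaln(alpha0.sum()) - gammaln(alpha0).sum()
               + ((alpha0 - 1) * elog_r).sum())
    f -= float(gammaln(a_sum) - gammaln(alpha).sum()
               + ((alpha - 1) * elog_r).sum())
    return f


def _free_energy_null(lme: np.ndarray) -> float:
    """Log evidence of the null model: all frequencies fixed at 1/K."""
    n, k = lme.shape
    return float(logsumexp(lme - np.log(k), axis=1).sum())


def rfx_bms(evidence: pd.DataFrame, mc_samples: int = 1_000_000,
            seed: Optional[int] = 0, tol: float = 1e-8,
            max_iter: int = 10_000) -> BMSResult:
    """Random-effects BMS with exceedance and protected exceedance
    probabilities.

    Parameters
    ----------
    evidence:
        Participants x models log model evidence (nats); rows may be
        shifted by any per-participant constant without changing the
        result.
    mc_samples:
        Dirichlet Monte-Carlo draws for the EP estimate (K > 2; for K = 2
        the analytic Beta tail is used).
    """
    models = list(evidence.columns)
    lme = np.asarray(evidence, dtype=float)
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidence matrix contains non-finite entries")
    n, k = lme.shape
    if k < 2:
        raise ValueError("need at least two models")
    if n < 2:
        import warnings
        warnings.warn("fewer than 2 participants: group-level inference "
                      "is degenerate", stacklevel=2)
    lme = lme - lme.max(axis=1, keepdims=True)  # row shift invariance

    alpha0 = np.ones(k)
    alpha = alpha0.copy()
    g = np.full((n, k), 1.0 / k)
    for it in range(1, max_iter + 1):
        elog_r = digamma(alpha) - digamma(alpha.sum())
        logu = lme + elog_r
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    expected_freq = alpha / alpha.sum()

    if k == 2:
        # P(r_1 > 0.5) for Beta(alpha_1, alpha_2): regularized incomplete beta
        tail = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        ep = np.array([tail, 1.0 - tail])
    else:
        rng = np.random.default_rng(seed)
        draws = rng.dirichlet(alpha, size=int(mc_samples))
        ep = np.bincount(np.argmax(draws, axis=1), minlength=k) / mc_samples

    f1 = _free_energy_rfx(lme, alpha, g, alpha0)
    f0 = _free_energy_null(lme)
    bor = float(1.0 / (1.0 + np.exp(np.clip(f1 - f0, -700, 700))))
    pep = ep * (1.0 - bor) + bor / k
    return BMSResult(models=models, alpha_post=alpha,
                     expected_freq=expected_freq, ep=ep, bor=bor, pep=pep,
                     n_iter=it)
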