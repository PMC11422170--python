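"""Scikit-learn-style estimators.

``ChoiceModel`` is a per-participant binary-choice model (any member of the
nine-model family) fitted by multistart bounded maximum likelihood;
``ArchetypeKMeans`` clusters participants' 100-condition intervention
profiles with silhouette-based selection of the cluster count.  Both follow
the sklearn estimator contract (``fit``, ``predict``/``predict_proba``,
``get_params``/``set_params``, fitted attributes with trailing underscores)
and compose with sklearn model-selection utilities.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from . import models as m

PROB_CLIP = 1e-12


def _nll_from_probs(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum())


class ChoiceModel(ClassifierMixin, BaseEstimator):
    """Maximum-likelihood fit of one choice model to one participant.

    Parameters
    ----------
    model:
        Model id, one of ``motivecocktail.models.MODEL_ORDER``.
    n_starts:
        Number of random starting points for the bounded local optimizer
        (independent uniform draws within each parameter's bounds).  The
        reference procedure uses 500; desk-scale analyses use 20-50.
    tol:
        Optimizer tolerance (L-BFGS-B ``ftol``-like).
    random_state:
        Seed for the start-point stream; fits are deterministic given it.

    Attributes
    ----------
    params_ : dict
        Best-fitting parameter values by name.
    nll_ : float
        Negative log-likelihood (nats) at the optimum.
    k_ : int
        Free-parameter count.
    n_ : int
        Trial count.
    aicc_ : float
        ``2*nll + 2k + 2k(k+1)/(n-k-1)``.
    best_start_index_ : int
        Index of the winning start.
    at_bounds_ : dict
        Per-parameter flag, True where the estimate sits on a bound.
    """

    def __init__(self, model: str = "cocktail", n_starts: int = 50,
                 tol: float = 1e-8, random_state: Optional[int] = None):
        self.model = model
        self.n_starts = n_starts
        self.tol = tol
        self.random_state = random_state

    # -- internal -----------------------------------------------------
    def _objective(self, feats: m.TrialFeatures, y: np.ndarray):
        names = m.MODEL_PARAMS[self.model]

        def nll(theta: np.ndarray) -> float:
            params = dict(zip(names, theta))
            p = m.choice_probability(self.model, params, feats)
            return _nll_from_probs(p, y)

        return nll

    def fit(self, X: pd.DataFrame, y: Sequence[int]) -> "ChoiceModel":
        """Fit to a tidy trial table ``X`` and 0/1 choice vector ``y``."""
        if self.model not in m.MODEL_PARAMS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        y = np.asarray(y, dtype=float)
        if len(X) != len(y) or len(y) == 0:
            raise ValueError("X and y must be non-empty and aligned")
        scen = set(X["scenario"]) if "scenario" in X else set()
        if self.model != "baseline" and len(scen) < 2:
            import warnings
            warnings.warn("single-scenario data: scenario-sensitive "
                          "parameters may be unidentifiable", stacklevel=2)
        feats = m.trial_features(X)
        names = m.MODEL_PARAMS[self.model]
        bounds = m.param_bounds(self.model)
        self.classes_ = np.array([0, 1])
        self.n_ = int(len(y))
        self.k_ = len(names)

        if self.model == "baseline":
            # Bernoulli rate: closed-form MLE.
            q = float(y.mean())
            self.params_ = {"q": q}
            self.nll_ = _nll_from_probs(np.full(self.n_, q), y)
            self.best_start_index_ = 0
            self.n_starts_used_ = 1
        else:
            rng = np.random.default_rng(self.random_state)
            nll = self._objective(feats, y)
            lo = np.array([b[0] for b in bounds])
            hi = np.array([b[1] for b in bounds])
            # Slope-like parameters (inverse temperature) are sampled
            # log-uniformly: a uniform draw on [0, 10] almost always lands
            # on the flat large-slope plateau where P(yes) saturates and
            # the gradient vanishes, which starves small multistart
            # budgets of informative starting points.
            log_dims = np.array([n in ("lambda", "temperature")
                                 for n in names])
            # deterministic anchor near the small-parameter corner (0 where
            # the bounds span it), where the likelihood surface is curved
            anchor = np.where((lo < 0) & (hi > 0), 0.0,
                              lo + 0.02 * (hi - lo))
            best = None
            n_fail = 0
            for s in range(self.n_starts):
                x0 = rng.uniform(lo, hi)
                if log_dims.any():
                    x0[log_dims] = 10.0 ** rng.uniform(-2, 1, log_dims.sum())
                if s == 0:
                    x0 = anchor.copy()
                try:
                    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                   options={"ftol": self.tol, "maxiter": 500})
                except (ValueError, FloatingPointError):
                    n_fail += 1
                    continue
                if not np.all(np.isfinite(res.x)):
                    n_fail += 1
                    continue
                if best is None or res.fun < best[0]:
                    best = (float(res.fun), res.x.copy(), s)
            if best is None:
                raise RuntimeError(
                    f"all {self.n_starts} optimizer starts failed "
                    f"({n_fail} exceptions) for model {self.model!r}")
            self.nll_, theta, self.best_start_index_ = best
            theta = np.clip(theta, lo, hi)
            self.params_ = dict(zip(names, (float(t) for t in theta)))
            self.n_starts_used_ = self.n_starts

        bdict = dict(zip(names, bounds))
        self.at_bounds_ = {
            p: bool(np.isclose(self.params_[p], bdict[p][0])
                    or np.isclose(self.params_[p], bdict[p][1]))
            for p in names
        }
        k, n = self.k_, self.n_
        self.aicc_ = 2.0 * self.nll_ + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = m.choice_probability(self.model, self.params_, m.trial_features(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X: pd.DataFrame, y: Sequence[int]) -> float:
        """Mean log-likelihood per trial (higher is better)."""
        p = self.predict_proba(X)[:, 1]
        return -_nll_from_probs(p, np.asarray(y, dtype=float)) / len(X)


class ArchetypeKMeans(ClusterMixin, BaseEstimator):
    """K-means over intervention profiles with silhouette-selected k.

    Runs Euclidean k-means at every k in ``k_range`` (``n_restarts``
    seeded restarts each), computes the mean silhouette, and keeps the k
    with the highest silhouette (ties broken toward smaller k).

    Attributes
    ----------
    k_ : int
        Selected number of clusters.
    labels_ : ndarray
        Cluster assignment per participant at the selected k.
    cluster_centers_ : ndarray
        Centroids at the selected k.
    silhouette_by_k_ : dict
        Mean silhouette per candidate k.
    """

    def __init__(self, k_range: Sequence[int] = tuple(range(2, 11)),
                 n_restarts: int = 100, random_state: Optional[int] = None):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None) -> "ArchetypeKMeans":
        X = np.asarray(X, dtype=float)
        ks = sorted(int(k) for k in self.k_range)
        if any(k < 2 for k in ks):
            raise ValueError("k_range must contain only k >= 2 "
                             "(silhouette undefined for k = 1)")
        if len(X) < max(ks) + 1:
            raise ValueError("need at least max(k_range) + 1 participants")
        sil = {}
        fits = {}
        for k in ks:
            km = KMeans(n_clusters=k, n_init=self.n_restarts,
                        random_state=self.random_state)
            labels = km.fit_predict(X)
            sil[k] = float(silhouette_score(X, labels)) \
                if len(set(labels)) > 1 else -1.0
            fits[k] = km
        # argmax silhouette, ties toward smaller k (ks is sorted)
        best_k = max(ks, key=lambda k: (sil[k], -k))
        self.k_ = best_k
        self.silhouette_by_k_ = sil
        self.labels_ = fits[best_k].labels_
        self.cluster_centers_ = fits[best_k].cluster_centers_
        self._km = fits[best_k]
        return self

    def predict(self, X) -> np.ndarray:
        return self._km.predict(np.asarray(X, dtype=float))
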