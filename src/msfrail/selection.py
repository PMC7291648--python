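"""Choosing the number of latent provider populations K.

The number of frailty support points is not identified by likelihood
maximization alone (the likelihood never decreases in K at the optimum), so K
is chosen in an outer loop over a grid: fit the EM at each K and compare
information criteria.  The free-parameter count is

    d = p + (K - 1) frailty parameters + (K - 1) mixing parameters,

the nonparametric baseline being profiled out.  BIC uses the number of
subjects in the transition dataset as the sample size (events or providers are
defensible alternatives; this is a documented convention, not an estimate).

A support-size heuristic is also provided: grow K until the fitted mixture
degenerates (a vanishing mixing proportion or two coincident support points)
and report the last non-degenerate K.  This style of rule tends to pick larger
K than BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .frailty_cox import (
    DiscreteFrailtyCoxPH,
    EMConfig,
    FrailtyCoxFit,
    fit_em,
    _WorkingData,
)

LAIRD_PI_TOL = 1e-3      # a component below this proportion is degenerate
LAIRD_LOGW_TOL = 1e-2    # two support points closer than this in log w coincide


def information_criteria(loglik: float, K: int, p: int, n: int) -> tuple[float, float]:
    """AIC and BIC for a K-population fit with p covariates and n subjects."""
    if n < 1:
        raise ValueError("n must be >= 1")
    d = p + (K - 1) + (K - 1)
    aic = -2.0 * loglik + 2.0 * d
    bic = -2.0 * loglik + d * np.log(n)
    return aic, bic


@dataclass
class SelectionResult:
    """Criteria table over the K grid plus the retained fit per criterion."""

    table: pd.DataFrame                    # columns K, loglik, n_params, aic, bic
    chosen_k: dict                         # criterion -> K
    best_fit: FrailtyCoxFit                # fit at the selected K (primary criterion)
    criterion: str
    fits: dict = field(default_factory=dict)   # K -> FrailtyCoxFit
    laird_k: int | None = None
    laird_reached_kmax: bool = False

    @property
    def best_k(self) -> int:
        return self.chosen_k[self.criterion]


def _is_degenerate(fit: FrailtyCoxFit) -> bool:
    pi, w = fit.params.pi, fit.params.w
    if (pi < LAIRD_PI_TOL).any():
        return True
    logw = np.sort(np.log(w))
    return bool(len(logw) > 1 and (np.diff(logw) < LAIRD_LOGW_TOL).any())


def select_k(data, k_max: int, config: EMConfig | None = None,
             criterion: str = "bic", compute_laird: bool = False) -> SelectionResult:
    """Fit K = 1..k_max and pick the K minimizing the chosen criterion.

    A K whose fit fails is recorded and skipped with a warning.  A drop in the
    maximized log-likelihood from K to K+1 signals a poor local optimum; the
    larger model is refitted once with fresh restarts and the better result
    kept.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    config = config or EMConfig()
    wd = _WorkingData.from_dataset(data)
    rows, fits = [], {}
    prev_ll = -np.inf
    for K in range(1, k_max + 1):
        try:
            fit = fit_em(wd, K, config)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"fit at K={K} failed and was skipped: {exc}")
            continue
        if fit.loglik < prev_ll - 1e-6:
            warnings.warn(
                f"log-likelihood decreased from K={K-1} to K={K}; refitting K={K}"
            )
            retry_cfg = EMConfig(
                tol=config.tol, max_iter=config.max_iter,
                n_restarts=config.n_restarts,
                init=config.init,
                seed=None if config.seed is None else config.seed + 7919 * K,
                m_step_cycles=config.m_step_cycles,
            )
            refit = fit_em(wd, K, retry_cfg)
            if refit.loglik > fit.loglik:
                fit = refit
        aic, bic = information_criteria(fit.loglik, K, wd.p, wd.n)
        rows.append({"K": K, "loglik": fit.loglik,
                     "n_params": wd.p + 2 * (K - 1), "aic": aic, "bic": bic})
        fits[K] = fit
        prev_ll = fit.loglik
    if not rows:
        raise RuntimeError("no K on the grid could be fitted")
    table = pd.DataFrame(rows)
    chosen = {
        "aic": int(table.loc[table["aic"].idxmin(), "K"]),
        "bic": int(table.loc[table["bic"].idxmin(), "K"]),
    }
    result = SelectionResult(
        table=table, chosen_k=chosen, best_fit=fits[chosen[criterion]],
        criterion=criterion, fits=fits,
    )
    if compute_laird and k_max >= 2:
        result.laird_k, result.laird_reached_kmax = _laird_from_fits(fits, k_max)
        result.chosen_k["laird"] = result.laird_k
    return result


def _laird_from_fits(fits: dict, k_max: int) -> tuple[int, bool]:
    last_good = 1
    for K in range(1, k_max + 1):
        if K not in fits:
            continue
        if _is_degenerate(fits[K]):
            return last_good, False
        last_good = K
    return last_good, True


def laird_support_size(data, k_max: int, config: EMConfig | None = None) -> tuple[int, bool]:
    """Support-size heuristic: grow K until the mixture degenerates.

    Returns (K, reached_kmax).  Degeneracy means some pi_k < 1e-3 or two
    support points with |log w_k - log w_k'| < 1e-2.  If k_max is reached with
    no degeneracy the flag is True and k_max is returned.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2 for the support-size heuristic")
    config = config or EMConfig()
    wd = _WorkingData.from_dataset(data)
    last_good = 1
    for K in range(1, k_max + 1):
        fit = fit_em(wd, K, config)
        if _is_degenerate(fit):
            return last_good, False
        last_good = K
    return k_max, True


class FrailtyCoxSelector(BaseEstimator):
    """Grid search over the number of latent populations.

    Fits :class:`DiscreteFrailtyCoxPH` for K = 1..``k_max`` and retains the fit
    minimizing ``criterion`` ('bic' by default, 'aic' available).

    Attributes
    ----------
    criteria_ : DataFrame with columns K, loglik, n_params, aic, bic.
    best_k_ : selected K under ``criterion``.
    chosen_k_ : dict criterion -> selected K (includes 'laird' if requested).
    best_estimator_ : fitted DiscreteFrailtyCoxPH at ``best_k_``.
    laird_k_, laird_reached_kmax_ : support-size heuristic output, if requested.
    """

    def __init__(self, k_max: int = 5, criterion: str = "bic",
                 compute_laird: bool = False, tol: float = 1e-6,
                 max_iter: int = 500, n_restarts: int = 5,
                 init: str = "random-partition", m_step_cycles: int = 2,
                 random_state: int | None = None):
        self.k_max = k_max
        self.criterion = criterion
        self.compute_laird = compute_laird
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.init = init
        self.m_step_cycles = m_step_cycles
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("groups (provider labels per row) is required")
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            feature_names = [f"x{i}" for i in range(X.shape[1])]
        time, event = DiscreteFrailtyCoxPH._split_y(y)
        wd = _WorkingData(time, event, X, groups)
        cfg = EMConfig(tol=self.tol, max_iter=self.max_iter,
                       n_restarts=self.n_restarts, init=self.init,
                       seed=self.random_state, m_step_cycles=self.m_step_cycles)
        res = select_k(wd, self.k_max, cfg, criterion=self.criterion,
                       compute_laird=self.compute_laird)
        self.selection_result_ = res
        self.criteria_ = res.table
        self.best_k_ = res.best_k
        self.chosen_k_ = res.chosen_k
        self.laird_k_ = res.laird_k
        self.laird_reached_kmax_ = res.laird_reached_kmax
        est = DiscreteFrailtyCoxPH(
            n_populations=res.best_k, tol=self.tol, max_iter=self.max_iter,
            n_restarts=self.n_restarts, init=self.init,
            m_step_cycles=self.m_step_cycles, random_state=self.random_state,
        )
        est.feature_names_in_ = np.asarray(feature_names, dtype=object)
        est._adopt(res.best_fit)
        self.best_estimator_ = est
        return self
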