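"""Cox proportional hazards with a nonparametric discrete shared frailty.

For one transition, subjects are nested in J providers and each provider j
belongs to one of K latent populations.  Conditional on membership k, subject
(i, j) has hazard

    lambda(t | X_ij, k) = lambda_0(t) * w_k * exp(X_ij' beta),

with w = (w_1, ..., w_K) the frailty support points, pi the mixing proportions
over populations, and lambda_0 an unspecified baseline.  Equivalently this is a
K-component mixture of proportional-hazards models sharing beta and baseline.
The model is fitted by EM:

  E-step   posterior membership alpha_jk of each provider, by Bayes rule;
  M-step   pi as posterior means; Breslow baseline increments with mixture
           weights; closed-form w update; one Newton step for beta on the
           expected complete-data log-likelihood (subjects replicated over
           components with case weight alpha_jk and offset log w_k).

Each M-step block maximizes the expected complete-data log-likelihood in its
own coordinate with the others fixed, so the observed log-likelihood is
non-decreasing (generalized EM).  Identifiability: w is reported sorted
ascending with w[0] = 1, the overall scale folded into the baseline.

Ties in event times use the Breslow approximation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .episodes import TransitionDataset

_PI_FLOOR = 1e-12  # floor for log(pi) only; a component below 1e-8 is flagged
_DEGENERATE_PI = 1e-8


@dataclass
class EMConfig:
    """Tuning knobs of the EM fit (all artifact-level choices)."""

    tol: float = 1e-6          # relative observed log-lik change to declare convergence
    max_iter: int = 500
    n_restarts: int = 5
    init: str = "random-partition"  # or "quantile-by-crude-rate"
    seed: int | None = None
    m_step_cycles: int = 2

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.init not in ("random-partition", "quantile-by-crude-rate"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class FrailtyCoxParams:
    """Parameters of the discrete-frailty Cox model for one transition.

    ``baseline_times`` are the distinct observed event times, ``baseline_hazard``
    the Breslow increments h_r there; the cumulative baseline is their running
    sum.  After fitting, w is ascending with w[0] = 1.
    """

    pi: np.ndarray
    w: np.ndarray
    beta: np.ndarray
    baseline_times: np.ndarray
    baseline_hazard: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.baseline_times = np.asarray(self.baseline_times, dtype=float)
        self.baseline_hazard = np.asarray(self.baseline_hazard, dtype=float)
        if self.pi.shape != self.w.shape:
            raise ValueError("pi and w must have the same length")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")
        if (self.w <= 0).any():
            raise ValueError("frailties must be strictly positive")
        if (self.baseline_hazard < 0).any():
            raise ValueError("baseline increments must be non-negative")

    @property
    def K(self) -> int:
        return len(self.pi)

    def cumulative_hazard(self, times) -> np.ndarray:
        """Lambda_0(t): running sum of increments at event times <= t."""
        cum = np.concatenate([[0.0], np.cumsum(self.baseline_hazard)])
        idx = np.searchsorted(self.baseline_times, np.asarray(times, dtype=float), side="right")
        return cum[idx]


class _WorkingData:
    """Preprocessed arrays for one transition dataset (internal)."""

    def __init__(self, time, event, X, groups):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != len(self.time):
            self.X = self.X.T
        self.group_labels, self.g = np.unique(np.asarray(groups), return_inverse=True)
        self.n, self.p = self.X.shape
        self.J = len(self.group_labels)
        if (self.time <= 0).any():
            raise ValueError("times must be strictly positive")
        ev = self.event == 1
        self.n_events = int(ev.sum())
        self.event_times, counts = np.unique(self.time[ev], return_counts=True)
        self.d = counts.astype(float)
        # risk-set bookkeeping: rows sorted ascending in time; risk set at t_r
        # is the suffix starting at the first row with time >= t_r
        self.order = np.argsort(self.time, kind="stable")
        self.time_sorted = self.time[self.order]
        self.risk_start = np.searchsorted(self.time_sorted, self.event_times, side="left")
        self.lam_idx = np.searchsorted(self.event_times, self.time, side="right")
        self.D_j = np.bincount(self.g, weights=self.event.astype(float), minlength=self.J)
        self.X_sorted = self.X[self.order]
        # row-wise outer products x x' of the time-sorted design, for the
        # Hessian suffix sums of the weighted partial likelihood
        self.XX_sorted = self.X_sorted[:, :, None] * self.X_sorted[:, None, :]

    @classmethod
    def from_dataset(cls, data) -> "_WorkingData":
        if isinstance(data, cls):
            return data
        if isinstance(data, TransitionDataset):
            return cls(data.time, data.event, data.X, data.groups)
        raise TypeError("expected a TransitionDataset or _WorkingData")

    def breslow_denominators(self, s: np.ndarray) -> np.ndarray:
        """Sum of per-row weights s over the risk set of each event time."""
        suffix = np.concatenate([np.cumsum(s[self.order][::-1])[::-1], [0.0]])
        return suffix[self.risk_start]


def _event_log_hazard(wd: _WorkingData, params: FrailtyCoxParams) -> np.ndarray:
    """log h(t_i) for event rows (0 elsewhere); errors on unsupported times."""
    out = np.zeros(wd.n)
    ev = wd.event == 1
    pos = np.searchsorted(params.baseline_times, wd.time[ev])
    bad = (
        (pos >= len(params.baseline_times))
        | (params.baseline_times[np.minimum(pos, len(params.baseline_times) - 1)] != wd.time[ev])
    )
    if bad.any():
        raise ValueError("event time not in the baseline support")
    h = params.baseline_hazard[pos]
    if (h <= 0).any():
        raise ValueError("event time with zero baseline increment: inconsistent baseline")
    out[ev] = np.log(h)
    return out


def _provider_component_loglik(wd: _WorkingData, params: FrailtyCoxParams):
    """Return the J x K matrix ell_jk of conditional provider log-likelihoods.

    ell_jk = sum_i [ delta_ij (log h(t_ij) + log w_k + X'beta)
                     - w_k exp(X'beta) Lambda_0(t_ij) ].
    """
    eta = wd.X @ params.beta
    logh = _event_log_hazard(wd, params)
    Lam = params.cumulative_hazard(wd.time)
    base_j = np.bincount(
        wd.g, weights=wd.event * (logh + eta), minlength=wd.J
    )
    H_j = np.bincount(wd.g, weights=np.exp(eta) * Lam, minlength=wd.J)
    logw = np.log(params.w)
    return base_j[:, None] + np.outer(wd.D_j, logw) - np.outer(H_j, params.w)


def observed_loglik(data, params: FrailtyCoxParams) -> float:
    """Observed-data log-likelihood: sum_j log sum_k pi_k exp(ell_jk).

    Computed with log-sum-exp over components for numerical safety.
    """
    wd = _WorkingData.from_dataset(data)
    ell = _provider_component_loglik(wd, params)
    return float(np.sum(logsumexp(np.log(np.maximum(params.pi, _PI_FLOOR)) + ell, axis=1)))


def e_step(data, params: FrailtyCoxParams) -> np.ndarray:
    """Posterior membership probabilities (J x K), Bayes rule per provider."""
    wd = _WorkingData.from_dataset(data)
    ell = _provider_component_loglik(wd, params)
    logpost = np.log(np.maximum(params.pi, _PI_FLOOR)) + ell
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    return np.exp(logpost)


def _suffix(a: np.ndarray) -> np.ndarray:
    """Suffix cumulative sums along axis 0, with a trailing zero row."""
    rev = np.cumsum(a[::-1], axis=0)[::-1]
    pad = np.zeros((1,) + a.shape[1:])
    return np.concatenate([rev, pad], axis=0)


def _profile_newton(wd, beta, m_row, tol=1e-10, max_iter=30, max_halvings=30):
    """Maximize the weighted Breslow partial likelihood in beta; return (beta, h).

    Profiling the baseline out of the expected complete-data log-likelihood
    (given posteriors and frailties, folded into the per-row weight ``m_row``)
    leaves pl(beta) = sum_i delta_i eta_i - sum_r d_r log S0(t_r) with
    S0(t_r) = sum over the risk set of m_i exp(eta_i).  Newton with step
    halving; the Breslow increments h_r = d_r / S0(t_r) are returned at the
    final beta, so (beta, h) jointly maximize the expected log-likelihood.
    """
    m_sorted = m_row[wd.order]
    delta_eta_x = wd.X.T @ wd.event  # sum of x over event rows

    def pl_and_s0(b):
        z = m_sorted * np.exp(wd.X_sorted @ b)
        s0 = _suffix(z)[wd.risk_start]
        pl = wd.event @ (wd.X @ b) - wd.d @ np.log(s0)
        return pl, z, s0

    pl, z, s0 = pl_and_s0(beta)
    for _ in range(max_iter):
        s1 = _suffix(z[:, None] * wd.X_sorted)[wd.risk_start]
        s2 = _suffix(z[:, None, None] * wd.XX_sorted)[wd.risk_start]
        xbar = s1 / s0[:, None]
        grad = delta_eta_x - wd.d @ xbar
        hess = np.einsum("r,rij->ij", wd.d, s2 / s0[:, None, None]) - (
            (wd.d[:, None] * xbar).T @ xbar
        )
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        scale = 1.0
        accepted = False
        for _ in range(max_halvings):
            cand = beta + scale * step
            with np.errstate(over="ignore"):
                pl_c, z_c, s0_c = pl_and_s0(cand)
            if np.isfinite(pl_c) and pl_c >= pl:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            break
        improved = pl_c - pl
        beta, pl, z, s0 = cand, pl_c, z_c, s0_c
        if improved < tol * (1.0 + abs(pl)):
            break
    h = wd.d / s0
    return beta, h, s0


def m_step(data, posteriors: np.ndarray, params: FrailtyCoxParams,
           n_cycles: int = 2) -> FrailtyCoxParams:
    """M-step: pi, then (Breslow baseline + beta) jointly, then w (cycled).

    Updates, with alpha the posterior matrix and m_i = sum_k alpha_{j(i)k} w_k:
      pi_k      = mean_j alpha_jk
      (beta, h) <- Newton on the m-weighted Breslow partial likelihood, the
                   baseline increments h_r = d_r / sum_{risk at t_r} m_i e^{eta_i}
                   profiled out at each step
      w_k       = [sum_j alpha_jk D_j] / [sum_j alpha_jk sum_i e^{eta_i} Lambda(t_i)]
                   (closed form)
    The cycle runs ``n_cycles`` times; each block maximizes the expected
    complete-data log-likelihood in its own coordinates given the others, so
    the observed log-likelihood cannot decrease.  Afterwards the components
    are sorted by w ascending and rescaled so w[0] = 1, the scale folded into
    the baseline.
    """
    wd = _WorkingData.from_dataset(data)
    alpha = np.asarray(posteriors, dtype=float)
    if alpha.shape[0] != wd.J:
        raise ValueError("posteriors must have one row per provider")
    pi = alpha.mean(axis=0)
    w = params.w.copy()
    beta = params.beta.copy()
    times = wd.event_times
    h = params.baseline_hazard.copy()
    for _ in range(n_cycles):
        m_row = (alpha @ w)[wd.g]
        beta, h, _ = _profile_newton(wd, beta, m_row)
        cum = np.concatenate([[0.0], np.cumsum(h)])
        Lam = cum[wd.lam_idx]
        ew = np.exp(wd.X @ beta)
        H_j = np.bincount(wd.g, weights=ew * Lam, minlength=wd.J)
        num = alpha.T @ wd.D_j
        den = alpha.T @ H_j
        w = np.where(den > 0, num / np.maximum(den, 1e-300), w)
        w = np.maximum(w, 1e-12)
    # identifiability: ascending w, w[0] = 1, scale into the baseline
    order = np.argsort(w)
    pi, w = pi[order], w[order]
    scale = w[0]
    w = w / scale
    h = h * scale
    return FrailtyCoxParams(pi=pi, w=w, beta=beta, baseline_times=times, baseline_hazard=h)


@dataclass
class FrailtyCoxFit:
    """Result of one EM fit at fixed K."""

    params: FrailtyCoxParams
    posteriors: np.ndarray
    assignments: np.ndarray          # 1-based labels, argmax of posteriors
    group_labels: np.ndarray         # provider ids, row order of posteriors
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    n_restarts_used: int
    seed: int | None
    beta_se: np.ndarray | None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "params": {
                "pi": self.params.pi.tolist(),
                "w": self.params.w.tolist(),
                "beta": self.params.beta.tolist(),
                "baseline_times": self.params.baseline_times.tolist(),
                "baseline_hazard": self.params.baseline_hazard.tolist(),
            },
            "posteriors": self.posteriors.tolist(),
            "assignments": self.assignments.tolist(),
            "group_labels": [str(x) for x in self.group_labels],
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "seed": self.seed,
            "beta_se": None if self.beta_se is None else self.beta_se.tolist(),
            "degenerate": self.degenerate,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _null_breslow(wd: _WorkingData) -> FrailtyCoxParams:
    """K=1 starting point: beta = 0, Breslow increments from raw risk counts."""
    h = wd.d / wd.breslow_denominators(np.ones(wd.n))
    return FrailtyCoxParams(
        pi=np.array([1.0]), w=np.array([1.0]), beta=np.zeros(wd.p),
        baseline_times=wd.event_times, baseline_hazard=h,
    )


def _run_em(wd, params, config: EMConfig):
    """Inner EM loop; returns (params, loglik, path, n_iter, converged)."""
    ll_prev = observed_loglik(wd, params)
    path = [ll_prev]
    converged = False
    for it in range(1, config.max_iter + 1):
        alpha = e_step(wd, params)
        params = m_step(wd, alpha, params, n_cycles=config.m_step_cycles)
        ll = observed_loglik(wd, params)
        if ll < ll_prev - 1e-9 * max(1.0, abs(ll_prev)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {ll_prev} -> {ll}"
            )
        path.append(ll)
        if abs(ll - ll_prev) < config.tol * max(1.0, abs(ll_prev)):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return params, ll_prev, np.array(path), len(path) - 1, converged


def _initial_params(wd, K, config, rng, null_params, oe):
    """Partition providers, set w from group-wise observed/expected ratios."""
    if config.init == "quantile-by-crude-rate":
        order = np.argsort(oe)
    else:
        order = rng.permutation(wd.J)
    blocks = np.array_split(order, K)
    w0 = np.array([max(float(np.mean(oe[b])), 1e-3) for b in blocks])
    w0 = np.sort(w0)
    # coincident starting points stall the split; nudge them apart
    for k in range(1, K):
        if w0[k] <= w0[k - 1] * (1 + 1e-3):
            w0[k] = w0[k - 1] * (1 + 0.05 * (1 + rng.random()))
    return FrailtyCoxParams(
        pi=np.full(K, 1.0 / K),
        w=w0,
        beta=null_params.beta.copy(),
        baseline_times=null_params.baseline_times,
        baseline_hazard=null_params.baseline_hazard.copy(),
    )


def fit_em(data, K: int, config: EMConfig | None = None) -> FrailtyCoxFit:
    """Fit the K-population discrete-frailty Cox model by restarted EM.

    Runs ``config.n_restarts`` initializations (random provider partitions,
    frailties seeded from group-wise observed/expected event ratios under a
    null Cox fit) and keeps the best final log-likelihood.  K=1 needs no
    restarts: the model reduces to a plain Cox fit with profiled baseline.
    """
    config = config or EMConfig()
    wd = _WorkingData.from_dataset(data)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > wd.J:
        raise ValueError(f"K={K} exceeds the number of providers J={wd.J}")
    if wd.n_events == 0:
        raise ValueError("no events in the dataset")

    rng = np.random.default_rng(config.seed)

    # null (K=1) fit: used directly for K=1 and as the seed for K>1 inits
    null_cfg = EMConfig(tol=config.tol, max_iter=config.max_iter, n_restarts=1,
                        seed=config.seed, m_step_cycles=config.m_step_cycles)
    null0 = _null_breslow(wd)
    null_params, null_ll, null_path, null_iter, null_conv = _run_em(wd, null0, null_cfg)

    if K == 1:
        best = (null_params, null_ll, null_path, null_iter, null_conv)
        n_restarts_used = 1
    else:
        eta = wd.X @ null_params.beta
        Lam = null_params.cumulative_hazard(wd.time)
        H_j = np.bincount(wd.g, weights=np.exp(eta) * Lam, minlength=wd.J)
        oe = np.where(H_j > 0, wd.D_j / np.maximum(H_j, 1e-300), 1.0)
        best = None
        n_restarts_used = config.n_restarts
        for r in range(config.n_restarts):
            init = _initial_params(wd, K, config, rng, null_params, oe)
            result = _run_em(wd, init, config)
            if best is None or result[1] > best[1]:
                best = result

    params, ll, path, n_iter, conv = best
    alpha = e_step(wd, params)
    assignments = np.argmax(alpha, axis=1) + 1
    degenerate = bool((params.pi < _DEGENERATE_PI).any())
    if degenerate:
        warnings.warn(
            f"EM fit at K={K}: a mixing proportion collapsed below {_DEGENERATE_PI}",
            RuntimeWarning,
        )
    beta_se = _beta_standard_errors(wd, params, alpha)
    return FrailtyCoxFit(
        params=params, posteriors=alpha, assignments=assignments,
        group_labels=wd.group_labels, loglik=ll, loglik_path=path,
        n_iter=n_iter, converged=conv, n_restarts_used=n_restarts_used,
        seed=config.seed, beta_se=beta_se, degenerate=degenerate,
    )


def _beta_standard_errors(wd, params, alpha):
    """SEs from the weighted-Cox information at convergence.

    Posteriors are treated as fixed case weights, so frailty-classification
    uncertainty is not propagated and the SEs understate the true variance.
    """
    m_row = (alpha @ params.w)[wd.g]
    z = m_row[wd.order] * np.exp(wd.X_sorted @ params.beta)
    s0 = _suffix(z)[wd.risk_start]
    s1 = _suffix(z[:, None] * wd.X_sorted)[wd.risk_start]
    s2 = _suffix(z[:, None, None] * wd.XX_sorted)[wd.risk_start]
    xbar = s1 / s0[:, None]
    info = np.einsum("r,rij->ij", wd.d, s2 / s0[:, None, None]) - (
        (wd.d[:, None] * xbar).T @ xbar
    )
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if (diag < 0).any():
            raise np.linalg.LinAlgError
        return np.sqrt(diag)
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; SEs unavailable", RuntimeWarning)
        return None


def frailty_ratios(fit: FrailtyCoxFit) -> np.ndarray:
    """w_k / w_1 with populations sorted ascending, so the vector starts at 1."""
    w = np.sort(fit.params.w)
    return w / w[0]


def hazard_ratios(fit: FrailtyCoxFit, names=None) -> pd.DataFrame:
    """Hazard ratios exp(beta) with delta-method standard errors."""
    beta = fit.params.beta
    hr = np.exp(beta)
    se = None if fit.beta_se is None else hr * fit.beta_se
    if names is None:
        names = [f"x{i}" for i in range(len(beta))]
    return pd.DataFrame({"covariate": names, "coef": beta, "hr": hr,
                         "se": se if se is not None else [np.nan] * len(beta)})


class DiscreteFrailtyCoxPH(BaseEstimator):
    """Proportional-hazards model with a K-point discrete shared frailty.

    scikit-learn style estimator.  ``fit(X, y, groups)`` takes a covariate
    matrix, survival outcomes and a provider label per row; providers are
    clustered into ``n_populations`` latent populations sharing a frailty.

    Parameters
    ----------
    n_populations : int
        Number of latent provider populations K.
    tol, max_iter, n_restarts, init, m_step_cycles
        EM controls, see :class:`EMConfig`.
    random_state : int or None
        Seed for the restart initializations.

    Attributes
    ----------
    coef_ : (p,) regression coefficients beta.
    coef_se_ : (p,) standard errors (posteriors treated as fixed weights).
    frailties_ : (K,) frailty support points, ascending, w[0] = 1.
    frailty_ratios_ : (K,) w_k / w_1 (equals ``frailties_`` after normalization).
    mixing_proportions_ : (K,) prior probabilities pi.
    baseline_hazard_ : pd.Series of Breslow increments indexed by event time.
    cumulative_baseline_hazard_ : pd.Series, running sum of the increments.
    posteriors_ : (J, K) provider membership probabilities.
    labels_ : (J,) 1-based Bayes-rule assignments, aligned with ``groups_``.
    groups_ : (J,) distinct provider identifiers.
    log_likelihood_ : observed-data log-likelihood at the optimum.
    """

    def __init__(self, n_populations: int = 1, tol: float = 1e-6,
                 max_iter: int = 500, n_restarts: int = 5,
                 init: str = "random-partition", m_step_cycles: int = 2,
                 random_state: int | None = None):
        self.n_populations = n_populations
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.init = init
        self.m_step_cycles = m_step_cycles
        self.random_state = random_state

    def _config(self) -> EMConfig:
        return EMConfig(tol=self.tol, max_iter=self.max_iter,
                        n_restarts=self.n_restarts, init=self.init,
                        seed=self.random_state, m_step_cycles=self.m_step_cycles)

    @staticmethod
    def _split_y(y):
        """Accept (time, event) tuples, 2-column arrays or structured arrays."""
        if isinstance(y, tuple) and len(y) == 2:
            return np.asarray(y[0], float), np.asarray(y[1], int)
        y = np.asarray(y)
        if y.dtype.names:
            names = y.dtype.names
            ev_name = next(n for n in names if y[n].dtype == bool or set(np.unique(y[n])) <= {0, 1})
            t_name = next(n for n in names if n != ev_name)
            return y[t_name].astype(float), y[ev_name].astype(int)
        if y.ndim == 2 and y.shape[1] == 2:
            return y[:, 0].astype(float), y[:, 1].astype(int)
        raise ValueError("y must be (time, event), a 2-column array or a structured array")

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("groups (provider labels per row) is required")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(X.shape[1])], dtype=object
            )
        time, event = self._split_y(y)
        wd = _WorkingData(time, event, X, groups)
        fit = fit_em(wd, self.n_populations, self._config())
        self._adopt(fit)
        return self

    def _adopt(self, fit: FrailtyCoxFit):
        """Populate fitted attributes from an existing EM fit."""
        self.fit_result_ = fit
        self.coef_ = fit.params.beta
        self.coef_se_ = fit.beta_se
        self.frailties_ = fit.params.w
        self.frailty_ratios_ = frailty_ratios(fit)
        self.mixing_proportions_ = fit.params.pi
        self.baseline_hazard_ = pd.Series(
            fit.params.baseline_hazard, index=fit.params.baseline_times, name="h"
        )
        self.cumulative_baseline_hazard_ = self.baseline_hazard_.cumsum()
        self.posteriors_ = fit.posteriors
        self.labels_ = fit.assignments
        self.groups_ = fit.group_labels
        self.log_likelihood_ = fit.loglik
        self.loglik_path_ = fit.loglik_path
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        return self

    def score(self, X, y, groups=None) -> float:
        """Observed-data log-likelihood of (X, y, groups) under the fitted model."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        time, event = self._split_y(y)
        wd = _WorkingData(time, event, X, groups)
        return observed_loglik(wd, self.fit_result_.params)

    def hazard_ratios(self) -> pd.DataFrame:
        return hazard_ratios(self.fit_result_, names=list(self.feature_names_in_))
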