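"""Multi-state orchestration: four transition fits, CIFs and pattern tables.

The four transitions are fitted independently (no frailty sharing across
transitions).  From the per-transition Bayes-rule assignments we form the
assignment matrix A (J providers x 4 transitions) and count how often each
combination of latent-population labels — a row of the configuration matrix C,
the Cartesian product of the per-transition label sets — occurs among
providers.

Cumulative incidence functions account for competing risks within each origin
state: for transition l with discrete hazard increments
lambda_l(t_r) = h_r * w_k * exp(X'beta),

    I_l(t) = sum_{r : t_r <= t} lambda_l(t_r) * S(t_{r-1}),

where S is the all-cause discrete survivor of the origin state,
S(t_r) = prod_{s <= r} (1 - sum_{l' out of the origin state} lambda_l'(t_s)),
evaluated model-based for the given covariate profile and populations.  With
no competing transition supplied, S reduces to the single-cause survivor and
I_l(t) -> 1 - exp(-Lambda_l(t)) as the event-time grid refines.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .episodes import (
    COVARIATE_COLUMNS,
    TRANSITION_LABELS,
    build_transition_datasets,
)
from .frailty_cox import FrailtyCoxFit
from .selection import EMConfig, SelectionResult, select_k

#: competing transition within each origin state
COMPETING = {1: 2, 2: 1, 3: 4, 4: 3}


@dataclass
class CIFCurve:
    """Model-based cumulative incidence of one transition for one profile."""

    transition: int
    population: int
    profile: np.ndarray
    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        if not self.label:
            self.label = TRANSITION_LABELS.get(self.transition, str(self.transition))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "cif": self.values})


def _profile_hazard(fit: FrailtyCoxFit, X, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Discrete hazard increments lambda(t_r) = h_r w_k exp(X'beta) on the fit grid."""
    if k < 1 or k > fit.params.K:
        raise ValueError(f"population {k} out of range 1..{fit.params.K}")
    X = np.asarray(X, dtype=float).ravel()
    lam = fit.params.baseline_hazard * fit.params.w[k - 1] * np.exp(X @ fit.params.beta)
    if (lam > 1).any():
        warnings.warn("discrete hazard increments above 1 were clipped", RuntimeWarning)
        lam = np.minimum(lam, 1.0)
    return fit.params.baseline_times.copy(), lam


def compute_cif(fit: FrailtyCoxFit, X, population: int,
                competing: list[tuple[FrailtyCoxFit, int]] | None = None,
                max_time: float | None = None) -> CIFCurve:
    """Cumulative incidence of one transition for a covariate profile.

    ``competing`` lists (fit, population) pairs for the other transitions out
    of the same origin state; their hazards enter the all-cause survivor.  With
    an empty list the curve is the single-cause incidence 1 - S_l(t).
    """
    times_own, lam_own = _profile_hazard(fit, X, population)
    grids = [times_own]
    comp_hazards = []
    for cfit, ck in competing or []:
        t_c, lam_c = _profile_hazard(cfit, X, ck)
        grids.append(t_c)
        comp_hazards.append((t_c, lam_c))
    grid = np.unique(np.concatenate(grids))
    if max_time is not None:
        grid = grid[grid <= max_time]

    def on_grid(t_src, lam_src):
        out = np.zeros(len(grid))
        pos = np.searchsorted(grid, t_src)
        keep = pos < len(grid)
        out[pos[keep]] = lam_src[keep]
        return out

    lam_l = on_grid(times_own, lam_own)
    lam_all = lam_l.copy()
    for t_c, lam_c in comp_hazards:
        lam_all += on_grid(t_c, lam_c)
    if (lam_all > 1).any():
        warnings.warn("all-cause hazard increments above 1 were clipped", RuntimeWarning)
        lam_all = np.minimum(lam_all, 1.0)
    surv_prev = np.concatenate([[1.0], np.cumprod(1.0 - lam_all)[:-1]])  # S(t_{r-1})
    cif = np.cumsum(lam_l * surv_prev)
    return CIFCurve(
        transition=fit_transition(fit), population=population,
        profile=np.asarray(X, dtype=float).ravel(),
        times=grid, values=cif,
    )


def fit_transition(fit: FrailtyCoxFit) -> int:
    """Transition id attached to a fit by the pipeline (0 if standalone)."""
    return getattr(fit, "transition", 0)


def enumerate_configurations(k_vector) -> np.ndarray:
    """All label combinations across transitions, lexicographic, 1-based.

    For K = (K_1, ..., K_L) the matrix has prod(K_l) rows and L columns.
    """
    ks = [int(k) for k in k_vector]
    if any(k < 1 for k in ks):
        raise ValueError("all K must be >= 1")
    return np.array(list(itertools.product(*(range(1, k + 1) for k in ks))), dtype=int)


def count_configuration_patterns(A, k_vector) -> pd.DataFrame:
    """Frequency of each latent-population pattern among providers.

    Returns the exhaustive configuration table sorted by count descending
    (ties in lexicographic order), with the percentage of the J providers to
    one decimal.  Counts sum to J.
    """
    A = np.asarray(A, dtype=int)
    ks = [int(k) for k in k_vector]
    if A.ndim != 2 or A.shape[1] != len(ks):
        raise ValueError("A must be J x L with L = len(k_vector)")
    for l, k in enumerate(ks):
        col = A[:, l]
        if ((col < 1) | (col > k)).any():
            raise ValueError(f"labels out of range 1..{k} in column {l}")
    C = enumerate_configurations(ks)
    J = A.shape[0]
    key = {tuple(row): i for i, row in enumerate(C)}
    counts = np.zeros(len(C), dtype=int)
    for row in A:
        counts[key[tuple(row)]] += 1
    table = pd.DataFrame(C, columns=[f"transition_{l+1}" for l in range(len(ks))])
    table["count"] = counts
    table["percent"] = [round(100.0 * c / J, 1) for c in counts]
    table = table.sort_values("count", ascending=False, kind="stable").reset_index(drop=True)
    return table


class MultiStateFrailtyModel(BaseEstimator):
    """Full pipeline: four discrete-frailty Cox fits with per-transition K.

    ``fit(episodes)`` takes a validated episode table, builds the four
    clock-reset transition datasets and runs the K-selection grid on each
    independently.  A transition with no events is flagged with selected K = 0
    and its assignment column fixed at 1.

    Parameters
    ----------
    k_max : int or dict {transition: int}
        Grid upper bound per transition.
    criterion : 'bic' or 'aic'.
    followup_days : administrative window used when follow-up end is missing.
    Remaining parameters are EM controls (see :class:`EMConfig`).

    Attributes
    ----------
    selections_ : dict transition -> SelectionResult (None if the fit failed).
    selected_k_ : dict transition -> chosen K (0 for a failed transition).
    assignment_matrix_ : (J, 4) int array A of Bayes-rule labels.
    providers_ : (J,) provider identifiers indexing the rows of A.
    datasets_ : dict transition -> TransitionDataset.
    """

    def __init__(self, k_max=5, criterion: str = "bic", compute_laird: bool = False,
                 followup_days: int = 1826, tol: float = 1e-6, max_iter: int = 500,
                 n_restarts: int = 5, init: str = "random-partition",
                 m_step_cycles: int = 2, random_state: int | None = None):
        self.k_max = k_max
        self.criterion = criterion
        self.compute_laird = compute_laird
        self.followup_days = followup_days
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.init = init
        self.m_step_cycles = m_step_cycles
        self.random_state = random_state

    def _k_max(self, transition: int) -> int:
        if isinstance(self.k_max, dict):
            return int(self.k_max[transition])
        return int(self.k_max)

    def fit(self, episodes: pd.DataFrame, y=None):
        datasets = build_transition_datasets(episodes, followup_days=self.followup_days)
        self.datasets_ = datasets
        providers = np.unique(episodes["provider_id"].to_numpy())
        self.providers_ = providers
        J = len(providers)
        self.selections_ = {}
        self.selected_k_ = {}
        A = np.ones((J, 4), dtype=int)
        for l in (1, 2, 3, 4):
            ds = datasets[l]
            seed = None if self.random_state is None else (self.random_state + l) % (2**31)
            cfg = EMConfig(tol=self.tol, max_iter=self.max_iter,
                           n_restarts=self.n_restarts, init=self.init,
                           seed=seed, m_step_cycles=self.m_step_cycles)
            if ds.n_events == 0:
                warnings.warn(
                    f"transition {l} ({TRANSITION_LABELS[l]}) has no events; flagged K=0"
                )
                self.selections_[l] = None
                self.selected_k_[l] = 0
                continue
            res = select_k(ds, self._k_max(l), cfg, criterion=self.criterion,
                           compute_laird=self.compute_laird)
            res.best_fit.transition = l
            for f in res.fits.values():
                f.transition = l
            self.selections_[l] = res
            self.selected_k_[l] = res.best_k
            # map the fit's provider order onto the global provider index;
            # providers absent from this transition keep the a-priori modal label
            fit = res.best_fit
            label_of = dict(zip(fit.group_labels, fit.assignments))
            default = int(np.argmax(fit.params.pi)) + 1
            A[:, l - 1] = [label_of.get(p, default) for p in providers]
        self.assignment_matrix_ = A
        return self

    @property
    def k_vector_(self) -> tuple:
        return tuple(max(self.selected_k_[l], 1) for l in (1, 2, 3, 4))

    def configuration_table(self) -> pd.DataFrame:
        """Pattern counts of the assignment matrix over all configurations."""
        return count_configuration_patterns(self.assignment_matrix_, self.k_vector_)

    def compute_cif(self, transition: int, X, population: int,
                    competing_population: int | None = None,
                    max_time: float | None = None) -> CIFCurve:
        """CIF for one transition, profile and latent population.

        The competing transition out of the same origin state enters the
        all-cause survivor; its population defaults to its modal (highest-pi)
        latent population when not given.
        """
        res = self.selections_.get(transition)
        if res is None:
            raise ValueError(f"transition {transition} was not fitted")
        comp_l = COMPETING[transition]
        comp_res = self.selections_.get(comp_l)
        competing = []
        if comp_res is not None:
            ck = competing_population
            if ck is None:
                ck = int(np.argmax(comp_res.best_fit.params.pi)) + 1
            competing.append((comp_res.best_fit, ck))
        return compute_cif(res.best_fit, X, population, competing, max_time=max_time)

    def cif_grid(self, transition: int, X, max_time: float | None = None) -> pd.DataFrame:
        """Long-format CIF curves for every latent population of a transition."""
        res = self.selections_.get(transition)
        if res is None:
            raise ValueError(f"transition {transition} was not fitted")
        frames = []
        for k in range(1, res.best_fit.params.K + 1):
            curve = self.compute_cif(transition, X, k, max_time=max_time)
            f = curve.to_frame()
            f.insert(0, "population", k)
            frames.append(f)
        out = pd.concat(frames, ignore_index=True)
        out.insert(0, "transition", transition)
        return out


def fit_multistate(episodes: pd.DataFrame, k_max=5, config: EMConfig | None = None,
                   criterion: str = "bic", followup_days: int = 1826) -> MultiStateFrailtyModel:
    """Functional wrapper over :class:`MultiStateFrailtyModel`."""
    config = config or EMConfig()
    model = MultiStateFrailtyModel(
        k_max=k_max, criterion=criterion, followup_days=followup_days,
        tol=config.tol, max_iter=config.max_iter, n_restarts=config.n_restarts,
        init=config.init, m_step_cycles=config.m_step_cycles,
        random_state=config.seed,
    )
    return model.fit(episodes)
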