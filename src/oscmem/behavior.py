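"""Object Space Task behavior: discrimination index and the uncertainty-driven
exploration-learning model.

The task places two identical objects in two of four corners of an open
field across repeated trials.  The model maintains a place-object
association strength ``w`` in [0, 1] per corner, updated by a delta rule
with learning rate ``alpha``::

    w_loc <- (1 - alpha) * w_loc + alpha * o_loc

where ``o_loc`` is 1 if an object occupies the corner this trial and 0
otherwise.  The association uncertainty ``U_loc = w_loc * (1 - w_loc)`` is
maximal for half-learned associations and vanishes for stable or absent
ones.  Exploration is allocated between the two present objects by a
softmax over their pre-update uncertainties with inverse temperature
``beta``; positive ``beta`` yields neophilic behavior (more time at the
uncertain/novel location), negative ``beta`` neophobic behavior.

Exploration time is discretized into 1 s units and the per-trial split is a
binomial draw with the softmax proportion, which yields a well-defined
likelihood; :class:`ExplorationModelMLE` recovers ``(alpha, beta)`` by
exhaustive grid search followed by Nelder-Mead refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .exceptions import ArgumentError, DegenerateTrialError, FitError

N_LOCATIONS = 4
CONDITIONS = ("stable", "overlapping", "random")

__all__ = [
    "TrialObservation",
    "TaskSession",
    "ModelFit",
    "discrimination_index",
    "model_step",
    "simulate_session",
    "session_nll",
    "fit_session",
    "design_for_condition",
    "ExplorationModelMLE",
]


@dataclass
class TrialObservation:
    """One trial: the two occupied corners and the time spent at each."""

    condition: str
    trial_index: int  # 1-based
    locations: tuple[int, int]  # corner ids in {1..4}, distinct
    explore_s: tuple[float, float]
    moved_slot: int | None = None  # which slot (0/1) holds the moved location

    def __post_init__(self) -> None:
        a, b = self.locations
        if a == b or not all(1 <= x <= N_LOCATIONS for x in (a, b)):
            raise ArgumentError("locations must be two distinct corners in 1..4")
        if any(t < 0 for t in self.explore_s):
            raise ArgumentError("exploration times must be nonnegative")


@dataclass
class TaskSession:
    condition: str
    trials: list[TrialObservation]
    subject: str | None = None


@dataclass
class ModelFit:
    alpha_hat: float
    beta_hat: float
    nll_min: float
    converged: bool
    grid_alpha: np.ndarray = field(repr=False, default=None)
    grid_beta: np.ndarray = field(repr=False, default=None)
    grid_nll: np.ndarray = field(repr=False, default=None)


def discrimination_index(explore_novel_s: float, explore_familiar_s: float) -> float:
    """DI = (novel - familiar) / (novel + familiar), in [-1, 1].

    Raises :class:`DegenerateTrialError` when total exploration is zero; a
    degenerate trial is flagged, never silently scored 0.
    """
    if explore_novel_s < 0 or explore_familiar_s < 0:
        raise ArgumentError("exploration times must be nonnegative")
    total = explore_novel_s + explore_familiar_s
    if total <= 0:
        raise DegenerateTrialError("zero total exploration: DI undefined")
    return (explore_novel_s - explore_familiar_s) / total


def _check_params(alpha: float, beta: float) -> None:
    if not (0.0 <= alpha <= 1.0):
        raise ArgumentError("alpha must lie in [0, 1]")
    if not np.isfinite(beta):
        raise ArgumentError("beta must be finite")


def model_step(
    w: np.ndarray,
    present_locations: tuple[int, int],
    alpha: float,
    beta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One trial of the model.

    Returns the updated memory vector and the exploration proportions over
    the two present locations, computed from the *pre-update* uncertainties.
    """
    _check_params(alpha, beta)
    a, b = present_locations
    if a == b or not all(1 <= x <= N_LOCATIONS for x in (a, b)):
        raise ArgumentError("present_locations must be two distinct corners")
    w = np.asarray(w, dtype=float)
    u = w * (1.0 - w)
    pair_u = np.array([u[a - 1], u[b - 1]])
    logits = beta * pair_u
    logits -= logits.max()  # stable softmax
    p = np.exp(logits)
    p /= p.sum()
    o = np.zeros(N_LOCATIONS)
    o[a - 1] = 1.0
    o[b - 1] = 1.0
    w_new = (1.0 - alpha) * w + alpha * o
    return w_new, p


def design_for_condition(
    condition: str,
    n_trials: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Per-trial corner pairs for a condition.

    stable: both corners fixed; overlapping: corner 1 fixed, the other moves
    each trial (never repeating the previous moved corner); random: both
    drawn fresh each trial.
    """
    if condition not in CONDITIONS:
        raise ArgumentError(f"unknown condition {condition!r}")
    if condition == "stable":
        return [(1, 2)] * n_trials
    if condition == "overlapping":
        design = []
        prev = None
        for _ in range(n_trials):
            choices = [c for c in (2, 3, 4) if c != prev]
            moved = int(rng.choice(choices))
            design.append((1, moved))
            prev = moved
        return design
    design = []
    for _ in range(n_trials):
        a, b = rng.choice(np.arange(1, N_LOCATIONS + 1), size=2, replace=False)
        design.append((int(a), int(b)))
    return design


def simulate_session(
    alpha: float,
    beta: float,
    design: list[tuple[int, int]],
    total_explore_s: float | list[float],
    rng: np.random.Generator,
    condition: str = "stable",
) -> TaskSession:
    """Simulate one session: binomial 1 s allocation at the model proportion.

    Memory starts at zero and is carried across trials within the session.
    """
    _check_params(alpha, beta)
    if not design:
        raise ArgumentError("design must list at least one trial")
    totals = (
        [float(total_explore_s)] * len(design)
        if np.isscalar(total_explore_s)
        else [float(t) for t in total_explore_s]
    )
    if len(totals) != len(design):
        raise ArgumentError("total_explore_s length must match design")
    w = np.zeros(N_LOCATIONS)
    trials = []
    for t, (locs, total) in enumerate(zip(design, totals), start=1):
        w, p = model_step(w, locs, alpha, beta)
        n = int(round(total))
        k = int(rng.binomial(n, p[0])) if n > 0 else 0
        trials.append(
            TrialObservation(
                condition=condition,
                trial_index=t,
                locations=locs,
                explore_s=(float(k), float(n - k)),
                moved_slot=1 if condition == "overlapping" else None,
            )
        )
    return TaskSession(condition=condition, trials=trials)


def _session_arrays(
    sessions: TaskSession | list[TaskSession],
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per session: (locations (n,2), k counts, n counts) for usable trials."""
    if isinstance(sessions, TaskSession):
        sessions = [sessions]
    out = []
    for sess in sessions:
        locs, ks, ns = [], [], []
        for tr in sess.trials:
            n = int(round(tr.explore_s[0] + tr.explore_s[1]))
            if n <= 0:
                continue  # degenerate trials carry no likelihood
            locs.append(tr.locations)
            ks.append(int(round(tr.explore_s[0])))
            ns.append(n)
        out.append((np.asarray(locs), np.asarray(ks), np.asarray(ns)))
    return out


def _uncertainty_traj(locs: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Pre-update uncertainties of the two present corners per trial.

    Vectorized over a grid of alphas: the memory trajectory depends only on
    alpha and the design, not on beta.  Returns (n_alpha, n_trials, 2).
    """
    n_alpha = alphas.size
    n_trials = locs.shape[0]
    w = np.zeros((n_alpha, N_LOCATIONS))
    out = np.empty((n_alpha, n_trials, 2))
    a_col = alphas[:, None]
    for t in range(n_trials):
        u = w * (1.0 - w)
        out[:, t, 0] = u[:, locs[t, 0] - 1]
        out[:, t, 1] = u[:, locs[t, 1] - 1]
        o = np.zeros(N_LOCATIONS)
        o[locs[t, 0] - 1] = 1.0
        o[locs[t, 1] - 1] = 1.0
        w = (1.0 - a_col) * w + a_col * o
    return out


def session_nll(
    alpha: float,
    beta: float,
    sessions: TaskSession | list[TaskSession],
) -> float:
    """Negative log-likelihood of the binomial allocation model.

    Trials with zero total exploration are skipped.  Finite for any
    ``alpha`` in [0, 1] and finite ``beta``.
    """
    _check_params(alpha, beta)
    nll = 0.0
    any_trial = False
    for locs, ks, ns in _session_arrays(sessions):
        if ns.size == 0:
            continue
        any_trial = True
        u = _uncertainty_traj(locs, np.array([alpha]))[0]  # (n_trials, 2)
        z = beta * u
        zmax = z.max(axis=1, keepdims=True)
        logz = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
        log_p1 = z[:, 0] - logz
        log_p2 = z[:, 1] - logz
        log_comb = gammaln(ns + 1) - gammaln(ks + 1) - gammaln(ns - ks + 1)
        nll -= float(np.sum(log_comb + ks * log_p1 + (ns - ks) * log_p2))
    if not any_trial:
        raise ArgumentError("no trial with positive total exploration")
    return nll


class ExplorationModelMLE(BaseEstimator):
    """Maximum-likelihood estimator for the exploration model (alpha, beta).

    Exhaustive grid search over ``alpha`` in [0, 1] and ``beta`` in
    [-beta_max, beta_max] (``n_grid`` points each), followed by Nelder-Mead
    refinement from the grid argmin.  Deterministic.

    Attributes
    ----------
    alpha_, beta_ : float
        Fitted parameters.
    nll_ : float
        Negative log-likelihood at the optimum.
    converged_ : bool
        Whether the local refinement converged.
    grid_nll_ : ndarray of shape (n_grid, n_grid)
        The full grid surface (alpha on axis 0).
    """

    def __init__(
        self,
        n_grid: int = 101,
        beta_max: float = 10.0,
        refine: bool = True,
    ) -> None:
        self.n_grid = n_grid
        self.beta_max = beta_max
        self.refine = refine

    def _grid_surface(
        self, sessions: TaskSession | list[TaskSession]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        alphas = np.linspace(0.0, 1.0, self.n_grid)
        betas = np.linspace(-self.beta_max, self.beta_max, self.n_grid)
        arrays = _session_arrays(sessions)
        if all(ns.size == 0 for _, _, ns in arrays):
            raise FitError("all trials degenerate: nothing to fit")
        nll = np.zeros((alphas.size, betas.size))
        for locs, ks, ns in arrays:
            if ns.size == 0:
                continue
            u = _uncertainty_traj(locs, alphas)  # (A, T, 2)
            # log-likelihood on the (A, B) grid via broadcasting over beta
            z = u[:, :, :, None] * betas[None, None, None, :]  # (A, T, 2, B)
            zmax = z.max(axis=2, keepdims=True)
            logz = zmax[:, :, 0, :] + np.log(
                np.exp(z - zmax).sum(axis=2)
            )  # (A, T, B)
            log_p1 = z[:, :, 0, :] - logz
            log_p2 = z[:, :, 1, :] - logz
            log_comb = gammaln(ns + 1) - gammaln(ks + 1) - gammaln(ns - ks + 1)
            ll = (
                log_comb[None, :, None]
                + ks[None, :, None] * log_p1
                + (ns - ks)[None, :, None] * log_p2
            )
            nll -= ll.sum(axis=1)
        return alphas, betas, nll

    def fit(self, sessions: TaskSession | list[TaskSession], y=None):
        alphas, betas, nll = self._grid_surface(sessions)
        # deterministic tie-break on flat ridges (e.g. alpha = 0 or equal
        # exploration make whole lines equivalent): among grid points within
        # float tolerance of the minimum prefer the smallest |beta| (weakest
        # memory expression consistent with the data), then smallest alpha.
        nll_min = float(nll.min())
        tied = np.argwhere(nll <= nll_min + 1e-9 * max(abs(nll_min), 1.0))
        order = np.lexsort(
            (alphas[tied[:, 0]], np.abs(betas[tied[:, 1]]))
        )
        ia, ib = tied[order[0]]
        alpha0, beta0 = float(alphas[ia]), float(betas[ib])
        best_nll = float(nll[ia, ib])
        converged = True
        if self.refine:

            def objective(theta: np.ndarray) -> float:
                a = float(np.clip(theta[0], 0.0, 1.0))
                b = float(np.clip(theta[1], -self.beta_max, self.beta_max))
                return session_nll(a, b, sessions)

            res = minimize(
                objective,
                x0=np.array([alpha0, beta0]),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
            )
            converged = bool(res.success)
            if res.fun <= best_nll:
                alpha0 = float(np.clip(res.x[0], 0.0, 1.0))
                beta0 = float(np.clip(res.x[1], -self.beta_max, self.beta_max))
                best_nll = float(res.fun)
        self.alpha_ = alpha0
        self.beta_ = beta0
        self.nll_ = best_nll
        self.converged_ = converged
        self.grid_alpha_ = alphas
        self.grid_beta_ = betas
        self.grid_nll_ = nll
        return self

    def score(self, sessions: TaskSession | list[TaskSession], y=None) -> float:
        """Mean log-likelihood per trial at the fitted parameters."""
        arrays = _session_arrays(sessions)
        n_trials = sum(ns.size for _, _, ns in arrays)
        return -session_nll(self.alpha_, self.beta_, sessions) / max(n_trials, 1)


def fit_session(
    sessions: TaskSession | list[TaskSession],
    n_grid: int = 101,
    beta_max: float = 10.0,
    refine: bool = True,
) -> ModelFit:
    """Functional wrapper around :class:`ExplorationModelMLE`."""
    est = ExplorationModelMLE(n_grid=n_grid, beta_max=beta_max, refine=refine).fit(
        sessions
    )
    return ModelFit(
        alpha_hat=est.alpha_,
        beta_hat=est.beta_,
        nll_min=est.nll_,
        converged=est.converged_,
        grid_alpha=est.grid_alpha_,
        grid_beta=est.grid_beta_,
        grid_nll=est.grid_nll_,
    )
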