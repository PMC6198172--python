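"""Nonlinear least-squares gLV fitting and forward stepwise coefficient selection.

A candidate model is defined by its *active set*: the ordered pairs (i, j)
whose interaction coefficients a_ij are free parameters (all other
off-diagonal entries are pinned at zero).  Growth rates are always free.
A fit minimizes the sum of squared relative-abundance residuals on a training
subset of time points; model comparison uses the Bayesian information
criterion evaluated on the *whole* series, so selection rewards both
descriptive and predictive power.

Forward stepwise selection starts from the growth-only model and greedily
adds the single coefficient or reciprocal pair {a_ij, a_ji} that lowers the
whole-series BIC the most, stopping when no addition lowers it further.
Near-ties (ΔBIC below a threshold) are broken uniformly at random, which is
deliberate: the instability it injects is what bootstrap aggregation averages
over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import least_squares

from ._integrate import OK, integrate_scaled
from .config import RunConfig
from .dynamics import AbundanceSeries, GLVParameters, SimulationError, simulate, to_relative

__all__ = [
    "ActiveSet",
    "FitResult",
    "CandidateModel",
    "rss",
    "bic",
    "fit_model",
    "stepwise_select",
]

_PENALTY = 1e3  # per-residual value substituted when a candidate's simulation fails
_MAX_STEPS_FIT = 20_000


@dataclass(frozen=True)
class ActiveSet:
    """Set of interaction coefficients a_ij that are free parameters.

    Entries are ordered index pairs (i, j) with i != j; (i, j) means the
    effect of taxon j on taxon i.
    """

    entries: frozenset = frozenset()

    def __post_init__(self):
        entries = frozenset((int(i), int(j)) for i, j in self.entries)
        if any(i == j for i, j in entries):
            raise ValueError("active set must not contain diagonal pairs")
        object.__setattr__(self, "entries", entries)

    @classmethod
    def of(cls, *pairs) -> "ActiveSet":
        return cls(frozenset(pairs))

    def add(self, pairs: Iterable) -> "ActiveSet":
        return ActiveSet(self.entries | {tuple(p) for p in pairs})

    def sorted(self) -> list:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.entries

    def __iter__(self):
        return iter(self.sorted())


@dataclass(frozen=True)
class FitResult:
    """Outcome of one constrained least-squares gLV fit.

    ``p0`` is the initial composition the fitted trajectory starts from —
    estimated when ``config.fit_initial_state`` is on, otherwise the observed
    (floored, renormalized) first row.
    """

    params: GLVParameters
    active: ActiveSet
    rss_train: float
    rss_full: float
    bic_full: float
    U: int
    V: int
    converged: bool
    p0: np.ndarray | None = None


@dataclass(frozen=True)
class CandidateModel:
    """One bootstrap round's selected model: active set, parameters, scores."""

    select_set: ActiveSet
    params: GLVParameters
    rss_full: float
    bic_full: float
    U: int
    V: int
    train_indices: tuple
    bootstrap_id: int = 0
    rng_seed: int = 0
    converged: bool = True
    p0: np.ndarray | None = None


def rss(observed: AbundanceSeries, predicted: AbundanceSeries) -> float:
    """Residual sum of squares between two relative-abundance series.

    Sums squared differences over every time point and taxon.  The two series
    must share the same taxa (in order) and the same time grid.
    """
    if observed.taxa != predicted.taxa:
        raise ValueError("taxon sets differ between observed and predicted series")
    if observed.times.shape != predicted.times.shape or not np.array_equal(
        observed.times, predicted.times
    ):
        raise ValueError("time grids differ between observed and predicted series")
    d = observed.P - predicted.P
    return float(np.sum(d * d))


def bic(rss_value: float, U: int, V: int, rss_floor: float = 1e-12) -> float:
    """Bayesian information criterion  U·ln(RSS/U) + ln(U)·V.

    ``U`` is the number of data points and ``V`` the number of free
    parameters; lower is better.  RSS values at or below ``rss_floor`` are
    floored to keep the logarithm finite on (near-)perfect fits.
    """
    if U < 1:
        raise ValueError("U must be at least 1")
    if V < 0:
        raise ValueError("V must be non-negative")
    if rss_value < 0:
        raise ValueError("RSS must be non-negative")
    r = max(float(rss_value), rss_floor)
    return U * math.log(r / U) + math.log(U) * V


def _seed_state(P0: np.ndarray, config: RunConfig) -> np.ndarray:
    """Initial scaled state y(t0) from the observed composition at t0.

    Zero observed fractions are floored at ``zero_floor`` (zero is absorbing
    in the model, so an exactly-zero start could never fit later nonzero
    observations); the row is renormalized, then scaled so the community
    starts at ``n0_fraction`` of carrying capacity.
    """
    p0 = np.maximum(np.asarray(P0, float), config.zero_floor)
    p0 = p0 / p0.sum()
    return p0 * config.n0_fraction


def _predict_relative(r, A, y0, times):
    """Relative-abundance prediction on ``times``; returns (P, ok)."""
    Y, status = integrate_scaled(r, A, y0, times, 1e-6, 1e-9, _MAX_STEPS_FIT)
    if status != OK or not np.all(np.isfinite(Y)):
        return None, False
    N = Y.sum(axis=1)
    n = Y.shape[1]
    P = np.empty_like(Y)
    good = N > 0
    P[good] = Y[good] / N[good, None]
    P[~good] = 1.0 / n
    return P, True


def fit_model(
    train: AbundanceSeries,
    active: ActiveSet,
    init: GLVParameters,
    config: RunConfig,
    full: AbundanceSeries | None = None,
    init_p0: np.ndarray | None = None,
) -> FitResult:
    """Fit growth rates and the active interaction coefficients to ``train``.

    Minimizes the sum of squared relative-abundance residuals on the training
    time points with a derivative-based least-squares solver (the
    Levenberg-Marquardt family; bounds r in ``config.r_bounds``, a_ij in
    ``config.a_bounds``).  Predictions come from simulating the community
    from the first training time point, seeded by the observed composition
    there (see ``_seed_state``).  RSS and BIC are then evaluated on ``full``
    (the whole series) — models are fitted to the training set but judged on
    all the data.

    A candidate whose simulation fails mid-optimization is penalized with
    large constant residuals rather than raising; a failure at the final
    parameters raises :class:`SimulationError`.
    """
    if train.n_times < 2:
        raise ValueError("training series needs at least 2 time points")
    if full is None:
        full = train
    n = train.n_taxa
    pairs = active.sorted()
    p_extra = len(pairs)
    p0_obs = _seed_state(train.P[0], config) / config.n0_fraction  # composition
    fit_p0 = bool(config.fit_initial_state) and n > 1
    n_w = n - 1 if fit_p0 else 0
    t_train = train.times
    P_train = train.P

    rows = np.array([i for i, _ in pairs], dtype=int)
    cols = np.array([j for _, j in pairs], dtype=int)

    def unpack(theta):
        r = theta[:n]
        A = np.zeros((n, n))
        if p_extra:
            A[rows, cols] = theta[n : n + p_extra]
        if fit_p0:
            # softmax over log-weights (first taxon's weight pinned at 0)
            w = np.concatenate([[0.0], theta[n + p_extra :]])
            e = np.exp(w - w.max())
            p0 = e / e.sum()
        else:
            p0 = p0_obs
        return r, A, p0

    def residuals(theta):
        r, A, p0 = unpack(theta)
        P_pred, ok = _predict_relative(r, A, p0 * config.n0_fraction, t_train)
        if not ok:
            return np.full(P_train.size, _PENALTY)
        return (P_pred - P_train).ravel()

    if fit_p0:
        p0_start = p0_obs if init_p0 is None else np.maximum(init_p0, config.zero_floor)
        p0_start = p0_start / p0_start.sum()
        w0 = np.log(p0_start[1:] / p0_start[0])
    else:
        w0 = np.empty(0)
    theta0 = np.concatenate(
        [
            np.asarray(init.r, float),
            np.array([init.A[i, j] for i, j in pairs], float),
            w0,
        ]
    )
    lo = np.concatenate(
        [
            np.full(n, config.r_bounds[0]),
            np.full(p_extra, config.a_bounds[0]),
            np.full(n_w, -16.0),
        ]
    )
    hi = np.concatenate(
        [
            np.full(n, config.r_bounds[1]),
            np.full(p_extra, config.a_bounds[1]),
            np.full(n_w, 16.0),
        ]
    )
    theta0 = np.clip(theta0, lo, hi)

    res = least_squares(
        residuals,
        theta0,
        bounds=(lo, hi),
        method="trf",
        ftol=config.opt_tol,
        xtol=config.opt_tol,
        gtol=config.opt_tol,
        max_nfev=config.max_iterations * (theta0.size + 1),
    )
    r_fit, A_fit, p0_fit = unpack(res.x)
    params = GLVParameters(train.taxa, r_fit, A_fit, config.carrying_capacity)
    y0 = p0_fit * config.n0_fraction

    U = full.n_times * n if config.u_convention == "tn" else full.n_times
    V = n + p_extra + n_w
    P_full, ok = _predict_relative(params.r, params.A, y0, full.times)
    if not ok:
        # explicit stiff-capable retry before declaring the candidate dead
        try:
            traj = simulate(params, y0 * config.carrying_capacity, full.times)
            P_full = to_relative(traj).P
        except SimulationError:
            raise SimulationError("fitted model cannot be simulated on the full series", params)
    rss_full = float(np.sum((P_full - full.P) ** 2))
    return FitResult(
        params=params,
        active=active,
        rss_train=float(2.0 * res.cost),
        rss_full=rss_full,
        bic_full=bic(rss_full, U, V, config.rss_floor),
        U=U,
        V=V,
        converged=bool(res.success),
        p0=p0_fit.copy(),
    )


def _default_init(taxa, n: int, config: RunConfig) -> GLVParameters:
    """Starting point of the selection loop: r_i = initial growth rate, a_ij = 0."""
    return GLVParameters(
        taxa,
        np.full(n, config.initial_growth_rate),
        np.zeros((n, n)),
        config.carrying_capacity,
    )


def stepwise_select(
    train: AbundanceSeries,
    full: AbundanceSeries,
    config: RunConfig,
    rng: np.random.Generator,
    bootstrap_id: int = 0,
    rng_seed: int = 0,
    train_indices: tuple = (),
) -> CandidateModel:
    """Forward stepwise selection of interaction coefficients under BIC.

    Starts from the growth-only model.  Each round fits, for every remaining
    single coefficient and every fully-remaining reciprocal pair
    {a_ij, a_ji}, the model augmented by that addition and scores it by
    whole-series BIC.  Candidate fits start from the standard cold
    initialization (r = 1/day, a = 0) by default: trajectory fits are
    multimodal, and warm starts from the incumbent were observed to land in
    worse optima and corrupt the greedy path; ``config.stepwise_starts``
    selects "cold", "warm", or best-of-"both".
    The addition with the lowest BIC is adopted; additions within
    ``config.bic_tie_delta`` of the round's lowest are ties, resolved
    uniformly at random with ``rng``.  Iteration stops when no addition
    lowers the current best BIC.  Per-candidate simulation failures count as
    BIC = +inf and never abort the round.
    """
    n = full.n_taxa
    current = fit_model(train, ActiveSet(), _default_init(full.taxa, n, config), config, full)
    best_bic = current.bic_full
    remaining = {(i, j) for i in range(n) for j in range(n) if i != j}

    while remaining:
        additions = [((i, j),) for (i, j) in sorted(remaining)]
        additions += [
            ((i, j), (j, i))
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) in remaining and (j, i) in remaining
        ]
        results = []
        cold = _default_init(full.taxa, n, config)
        for add in additions:
            cand_active = current.active.add(add)
            # trajectory fits are multimodal: try both the warm start from the
            # incumbent fit and the default cold start, keep the better optimum
            fits = []
            starts = {
                "both": ((current.params, current.p0), (cold, None)),
                "warm": ((current.params, current.p0),),
                "cold": ((cold, None),),
            }[config.stepwise_starts]
            for init, ip0 in starts:
                try:
                    fits.append(
                        fit_model(train, cand_active, init, config, full, init_p0=ip0)
                    )
                except SimulationError:
                    pass
            fit = min(fits, key=lambda f: f.bic_full) if fits else None
            results.append((math.inf if fit is None else fit.bic_full, add, fit))

        round_best = min(b for b, _, _ in results)
        if not (round_best < best_bic):
            break
        # ties must themselves lower the current best BIC, so the accepted
        # trace stays strictly decreasing even under random tie-breaking
        best_k = min(range(len(results)), key=lambda k: results[k][0])
        ties = [
            k
            for k, (b, _, _) in enumerate(results)
            if b - round_best < config.bic_tie_delta and b < best_bic
        ]
        if config.bic_tie_delta > 0 and len(ties) > 1:
            choice = ties[int(rng.integers(len(ties)))]
        else:
            choice = best_k
        _, added, current = results[choice]
        best_bic = current.bic_full
        remaining -= set(added)

    return CandidateModel(
        select_set=current.active,
        params=current.params,
        rss_full=current.rss_full,
        bic_full=current.bic_full,
        U=current.U,
        V=current.V,
        train_indices=tuple(int(i) for i in train_indices),
        bootstrap_id=bootstrap_id,
        rng_seed=rng_seed,
        converged=current.converged,
        p0=current.p0,
    )
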