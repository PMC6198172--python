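"""Bootstrap aggregation of stepwise-selected gLV models.

Forward stepwise selection is unstable: small perturbations of the data (or
the random tie-breaks) change which coefficients are selected.  The remedy is
bagging — repeat (random train/test partition → stepwise selection) many
times, filter out biologically implausible models, keep the best-BIC slice,
and call an interaction significant when its coefficient values across the
retained models differ from zero by a one-sample t-test.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import RunConfig
from .dynamics import AbundanceSeries, SimulationError, simulate
from .fitting import CandidateModel, _seed_state, stepwise_select

__all__ = [
    "ModelEnsemble",
    "AggregatedCoefficient",
    "partition",
    "run_bagging",
    "filter_models",
    "select_best",
    "aggregate_and_test",
]


@dataclass(frozen=True)
class ModelEnsemble:
    """Collection of candidate models from bootstrap rounds.

    ``filter_log`` records one (bootstrap_id, reason) entry per model removed
    by biological filtering; failed rounds are counted in ``n_failed``.
    """

    models: tuple
    n_requested: int
    n_failed: int = 0
    filter_log: tuple = ()

    def __len__(self) -> int:
        return len(self.models)

    @property
    def bics(self) -> np.ndarray:
        return np.array([m.bic_full for m in self.models])


@dataclass(frozen=True)
class AggregatedCoefficient:
    """Aggregate of one interaction coefficient a_ij across retained models."""

    pair: tuple
    values: np.ndarray
    mean: float
    t_statistic: float
    p_value: float
    selection_frequency: float
    significant: bool


def partition(
    series: AbundanceSeries, train_fraction: float, rng: np.random.Generator
):
    """Random train/test split of time points for one bootstrap round.

    The training set holds ``round(train_fraction * T)`` time points sampled
    without replacement, always including the first time point (it seeds
    every simulation), returned in temporal order; the test set is the
    complement.  Returns ``(train, test, train_indices)``.
    """
    T = series.n_times
    if T < 3:
        raise ValueError("need at least 3 time points to partition")
    n_train = int(math.floor(train_fraction * T + 0.5))
    if n_train < 2:
        raise ValueError(
            f"train_fraction {train_fraction} keeps fewer than 2 of {T} time points"
        )
    n_train = min(n_train, T)
    rest = rng.choice(np.arange(1, T), size=n_train - 1, replace=False)
    idx = np.sort(np.concatenate([[0], rest])).astype(int)
    test_idx = np.setdiff1d(np.arange(T), idx)
    train = series.subset(idx)
    test = series.subset(test_idx) if test_idx.size else None
    return train, test, tuple(int(i) for i in idx)


def _child_seed(master_seed: int, i: int) -> tuple:
    """Counter-based per-round seed: independent streams, order-free."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(i),))
    return ss, int(ss.generate_state(1)[0])


def _one_round(series, config: RunConfig, i: int):
    ss, seed_int = _child_seed(config.master_seed, i)
    rng = np.random.default_rng(ss)
    if isinstance(series, (list, tuple)):
        # multi-subject mode: each round draws one subject's series
        series = series[int(rng.integers(len(series)))]
    train, _test, idx = partition(series, config.train_fraction, rng)
    try:
        return stepwise_select(
            train,
            series,
            config,
            rng,
            bootstrap_id=i,
            rng_seed=seed_int,
            train_indices=idx,
        )
    except SimulationError:
        return None


def run_bagging(
    series,
    config: RunConfig,
    n_bootstraps: int | None = None,
    threads: int = 1,
) -> ModelEnsemble:
    """Run ``n_bootstraps`` independent (partition → stepwise) rounds.

    ``series`` may be a single :class:`AbundanceSeries` or a list of
    per-subject series sharing the same taxa, in which case each round first
    draws one subject and then partitions within it.  Each round draws its
    own random stream from the master seed by a counter-based scheme, so the
    ensemble is identical for a fixed master seed regardless of execution
    order or thread count.  Rounds whose fits fail are counted in
    ``n_failed``.
    """
    n = config.n_bootstraps if n_bootstraps is None else int(n_bootstraps)
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(lambda i: _one_round(series, config, i), range(n)))
    else:
        results = [_one_round(series, config, i) for i in range(n)]
    models = tuple(m for m in results if m is not None)
    return ModelEnsemble(models=models, n_requested=n, n_failed=n - len(models))


def filter_models(ensemble: ModelEnsemble, config: RunConfig, series: AbundanceSeries) -> ModelEnsemble:
    """Remove models violating biological constraints.

    Each model is simulated over the observed time span from the standard
    initial state; a model that drives any taxon below
    ``config.min_species_abundance`` or the community below
    ``config.min_community_size`` (absolute units) at any output time is
    removed and logged.  Thresholds of 0 disable the corresponding check, so
    filtering with both at 0 is the identity.  Idempotent.
    """
    min_x = config.min_species_abundance
    min_n = config.min_community_size
    if min_x <= 0 and min_n <= 0:
        return ensemble
    kept = []
    log = list(ensemble.filter_log)
    x0 = _seed_state(series.P[0], config) * config.carrying_capacity
    for m in ensemble.models:
        try:
            traj = simulate(m.params, x0, series.times)
        except SimulationError:
            log.append((m.bootstrap_id, "simulation failed during filtering"))
            continue
        reason = None
        if min_x > 0:
            tmin, imin = np.unravel_index(np.argmin(traj.X), traj.X.shape)
            if traj.X[tmin, imin] < min_x:
                reason = (
                    f"taxon {series.taxa[imin]} fell below min abundance at "
                    f"t={traj.times[tmin]:g}"
                )
        if reason is None and min_n > 0:
            N = traj.N
            tmin = int(np.argmin(N))
            if N[tmin] < min_n:
                reason = f"community size fell below minimum at t={traj.times[tmin]:g}"
        if reason is None:
            kept.append(m)
        else:
            log.append((m.bootstrap_id, reason))
    return ModelEnsemble(
        models=tuple(kept),
        n_requested=ensemble.n_requested,
        n_failed=ensemble.n_failed,
        filter_log=tuple(log),
    )


def select_best(ensemble: ModelEnsemble, allowance: float = 0.10, mode: str = "relative") -> ModelEnsemble:
    """Keep the minimum-BIC slice of the ensemble.

    With B* the minimum BIC over retained models, keeps models with
    BIC ≤ B* + allowance·|B*| (relative mode; the absolute value makes the
    band widen upward also when BIC is negative, the common case here) or
    BIC ≤ B* + allowance (absolute mode).
    """
    if len(ensemble) == 0:
        raise ValueError(
            "no models to select from — relax the biological constraints or "
            "increase the number of bootstraps"
        )
    bics = ensemble.bics
    b_star = bics.min()
    cutoff = b_star + allowance * abs(b_star) if mode == "relative" else b_star + allowance
    kept = tuple(m for m, b in zip(ensemble.models, bics) if b <= cutoff)
    return ModelEnsemble(
        models=kept,
        n_requested=ensemble.n_requested,
        n_failed=ensemble.n_failed,
        filter_log=ensemble.filter_log,
    )


def _one_sample_t(values: np.ndarray):
    """Two-sided one-sample t-test of mean != 0 with zero-variance conventions.

    A constant all-zero sample is maximally consistent with no interaction
    (p = 1); a constant nonzero sample is maximally inconsistent (p = 0).
    """
    m = values.size
    mean = float(values.mean())
    constant = bool(np.all(values == values[0]))
    sd = float(values.std(ddof=1)) if m > 1 else 0.0
    if constant or sd == 0.0 or m < 2:
        if mean == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    t = mean / (sd / math.sqrt(m))
    p = 2.0 * stats.t.sf(abs(t), df=m - 1)
    return float(t), float(p)


def aggregate_and_test(
    ensemble: ModelEnsemble,
    confidence: float = 0.95,
    include_unselected_zeros: bool = True,
):
    """Compile parameters across retained models and call significance.

    For every ordered pair (i, j) the t-test sample is the coefficient's
    value in each retained model — exactly 0 where the model did not select
    the pair (a coefficient absent from a model is zero in that model by
    construction); set ``include_unselected_zeros=False`` to test only the
    selecting models' values.  Significant ⇔ two-sided p < 1 - confidence.

    Returns ``(coefficients, growth)`` where ``coefficients`` is a list of
    :class:`AggregatedCoefficient` over all ordered pairs and ``growth`` a
    dict taxon -> (mean growth rate, standard error).  With a single retained
    model significance is undefined: means are reported, p-values are NaN and
    nothing is significant.
    """
    if len(ensemble) == 0:
        raise ValueError("cannot aggregate an empty ensemble")
    models = ensemble.models
    taxa = models[0].params.taxa
    n = len(taxa)
    m = len(models)
    alpha = 1.0 - confidence

    A_stack = np.stack([mod.params.A for mod in models])
    sel_stack = np.zeros((m, n, n), dtype=bool)
    for k, mod in enumerate(models):
        for (i, j) in mod.select_set:
            sel_stack[k, i, j] = True

    coefficients = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            all_vals = A_stack[:, i, j]
            freq = float(sel_stack[:, i, j].mean())
            if include_unselected_zeros:
                sample = all_vals
            else:
                sample = all_vals[sel_stack[:, i, j]]
            if sample.size == 0:
                mean_v, t, p = 0.0, 0.0, 1.0
            elif m < 2 or (not include_unselected_zeros and sample.size < 2):
                mean_v, t, p = float(sample.mean()), math.nan, math.nan
            else:
                mean_v = float(sample.mean())
                t, p = _one_sample_t(sample)
            coefficients.append(
                AggregatedCoefficient(
                    pair=(i, j),
                    values=all_vals.copy(),
                    mean=mean_v,
                    t_statistic=t,
                    p_value=p,
                    selection_frequency=freq,
                    significant=bool(p < alpha) if not math.isnan(p) else False,
                )
            )

    R_stack = np.stack([mod.params.r for mod in models])
    growth = {}
    for i, taxon in enumerate(taxa):
        vals = R_stack[:, i]
        se = float(vals.std(ddof=1) / math.sqrt(m)) if m > 1 else math.nan
        growth[taxon] = (float(vals.mean()), se)
    return coefficients, growth
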