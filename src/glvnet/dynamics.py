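"""Generalized Lotka-Volterra community dynamics.

The model describes ``n`` interacting taxa whose absolute abundances
``x_i(t)`` obey

    dx_i/dt = x_i * (r_i + sum_j a_ij * x_j / N) * (1 - N / K),

where ``N = sum_i x_i`` is the community size, ``r_i`` the intrinsic growth
rate of taxon ``i`` (1/day), ``a_ij`` the per-capita effect of taxon ``j`` on
taxon ``i`` weighted by j's relative abundance, and ``K`` a community-wide
carrying capacity (cells or CFU per gram).  Intra-taxon terms (the diagonal of
``A``) are excluded; density regulation enters only through the shared
logistic factor ``(1 - N/K)``.

Observations from sequencing or plate counts are compositional, so the
observable object is the relative-abundance series ``P[t, i] = x_i(t)/N(t)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from ._integrate import FAILED, integrate_scaled

__all__ = [
    "GLVParameters",
    "Trajectory",
    "AbundanceSeries",
    "SimulationError",
    "glv_rhs",
    "simulate",
    "to_relative",
]


class SimulationError(RuntimeError):
    """Raised when numerical integration of a gLV system fails.

    Carries the offending parameter set so the fitting layer can log it and
    penalize the candidate (treated as an infinite-RSS model) instead of
    aborting the whole selection run.
    """

    def __init__(self, message: str, params: "GLVParameters | None" = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class GLVParameters:
    """Parameters of a gLV community model.

    Attributes
    ----------
    taxa : tuple of str
        Ordered taxon identifiers (length n).
    r : ndarray, shape (n,)
        Intrinsic growth rates, 1/day.
    A : ndarray, shape (n, n)
        Interaction matrix; ``A[i, j]`` is the effect of taxon j on taxon i.
        The diagonal is identically zero (no intra-taxon interactions).
    K : float
        Community carrying capacity, cells (or CFU) per gram.
    """

    taxa: tuple
    r: np.ndarray
    A: np.ndarray
    K: float

    def __post_init__(self):
        taxa = tuple(str(t) for t in self.taxa)
        r = np.asarray(self.r, dtype=float)
        A = np.asarray(self.A, dtype=float)
        n = len(taxa)
        if n < 1:
            raise ValueError("at least one taxon is required")
        if r.shape != (n,):
            raise ValueError(f"r has shape {r.shape}, expected ({n},)")
        if A.shape != (n, n):
            raise ValueError(f"A has shape {A.shape}, expected ({n}, {n})")
        if not np.all(np.isfinite(r)):
            raise ValueError("growth rates must be finite")
        if not np.all(np.isfinite(A)):
            raise ValueError("interaction coefficients must be finite")
        if np.any(np.diagonal(A) != 0.0):
            raise ValueError("diagonal of A must be zero (no intra-taxon terms)")
        if not (self.K > 0):
            raise ValueError("carrying capacity K must be positive")
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "A", A)
        r.setflags(write=False)
        A.setflags(write=False)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def with_updates(self, r=None, A=None) -> "GLVParameters":
        """Copy with replaced growth-rate vector and/or interaction matrix."""
        return replace(
            self,
            r=self.r if r is None else np.asarray(r, float),
            A=self.A if A is None else np.asarray(A, float),
        )


@dataclass(frozen=True)
class Trajectory:
    """Absolute-abundance solution of a gLV system on a time grid.

    ``X[t, i]`` is the abundance of taxon i at ``times[t]`` (cells/g);
    ``N`` is the community size, the row sums of ``X`` by construction.
    """

    taxa: tuple
    times: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be a strictly increasing 1-d array")
        if X.shape != (times.size, len(self.taxa)):
            raise ValueError("X must have shape (len(times), n_taxa)")
        if np.any(X < 0):
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "taxa", tuple(str(t) for t in self.taxa))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "X", X)

    @property
    def N(self) -> np.ndarray:
        """Community size per time point."""
        return self.X.sum(axis=1)


@dataclass(frozen=True)
class AbundanceSeries:
    """Observed (or predicted) relative-abundance time series.

    ``P[t, i]`` is the fraction of taxon i at ``times[t]``; each row sums to 1.
    ``degenerate`` flags rows that came from an empty community (N = 0) and
    were filled uniformly.
    """

    taxa: tuple
    times: np.ndarray
    P: np.ndarray
    degenerate: np.ndarray = field(default=None, compare=False)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        P = np.asarray(self.P, dtype=float)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be a strictly increasing 1-d array")
        if P.shape != (times.size, len(self.taxa)):
            raise ValueError("P must have shape (len(times), n_taxa)")
        if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
            raise ValueError("relative abundances must lie in [0, 1]")
        sums = P.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise ValueError("each time point's relative abundances must sum to 1")
        deg = self.degenerate
        deg = np.zeros(times.size, bool) if deg is None else np.asarray(deg, bool)
        object.__setattr__(self, "taxa", tuple(str(t) for t in self.taxa))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "degenerate", deg)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_times(self) -> int:
        return self.times.size

    def subset(self, indices) -> "AbundanceSeries":
        """Series restricted to the given time-point indices (sorted)."""
        idx = np.sort(np.asarray(indices, dtype=int))
        return AbundanceSeries(
            self.taxa, self.times[idx], self.P[idx], self.degenerate[idx]
        )

    def to_dataframe(self):
        """Taxa-by-time DataFrame (columns = times in days)."""
        import pandas as pd

        return pd.DataFrame(self.P.T, index=list(self.taxa), columns=self.times)


def glv_rhs(params: GLVParameters, x: np.ndarray) -> np.ndarray:
    """Right-hand side dx/dt of the gLV system at state ``x`` (absolute units).

    The empty community is absorbing: N = 0 returns the zero vector.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n,):
        raise ValueError(f"x has shape {x.shape}, expected ({params.n},)")
    N = x.sum()
    if N <= 0:
        return np.zeros(params.n)
    return x * (params.r + params.A @ (x / N)) * (1.0 - N / params.K)


_MAX_STEPS = 100_000


def simulate(
    params: GLVParameters,
    x0: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-6,
    atol_scaled: float = 1e-9,
) -> Trajectory:
    """Integrate the gLV system from ``x0`` and return the trajectory at ``times``.

    Integration is performed in carrying-capacity units (y = x/K) with an
    adaptive Dormand-Prince 5(4) stepper; parameter sets that defeat the
    explicit stepper are retried with LSODA, which handles stiffness.  The
    absolute tolerance ``atol_scaled`` applies to y, i.e. it equals
    ``atol_scaled * K`` in abundance units.  Negative solver excursions are
    clamped to zero.  Deterministic for fixed inputs.

    Raises
    ------
    SimulationError
        If both integrators fail; carries the parameter set.  The fitting
        layer treats this as an infinite-RSS candidate.
    """
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if x0.shape != (params.n,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({params.n},)")
    if np.any(x0 < 0):
        raise ValueError("x0 must be non-negative")
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing with at least one entry")

    y0 = x0 / params.K
    if times.size == 1:
        return Trajectory(params.taxa, times, (y0 * params.K)[None, :].copy())

    Y, status = integrate_scaled(
        params.r, params.A, y0, times, rtol, atol_scaled, _MAX_STEPS
    )
    if status == FAILED:
        Y = _simulate_lsoda(params, y0, times, rtol, atol_scaled)
    if not np.all(np.isfinite(Y)):
        raise SimulationError("non-finite state during gLV integration", params)
    return Trajectory(params.taxa, times, np.clip(Y, 0.0, None) * params.K)


def _simulate_lsoda(params, y0, times, rtol, atol):
    r, A = params.r, params.A

    def rhs(t, y):
        yc = np.clip(y, 0.0, None)
        N = yc.sum()
        if N <= 0:
            return np.zeros_like(y)
        return yc * (r + A @ (yc / N)) * (1.0 - N)

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or sol.y.shape[1] != times.size:
        raise SimulationError(f"gLV integration failed: {sol.message}", params)
    return sol.y.T


def to_relative(traj: Trajectory) -> AbundanceSeries:
    """Convert a trajectory to relative abundances.

    Rows with an empty community (N = 0) are returned as the uniform
    composition 1/n and flagged in ``degenerate`` (with a warning).
    """
    N = traj.N
    n = len(traj.taxa)
    degenerate = N <= 0
    P = np.empty_like(traj.X)
    good = ~degenerate
    P[good] = traj.X[good] / N[good, None]
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} time point(s) have zero community size; "
            "returning uniform composition for those rows",
            RuntimeWarning,
            stacklevel=2,
        )
        P[degenerate] = 1.0 / n
    return AbundanceSeries(traj.taxa, traj.times, P, degenerate)
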