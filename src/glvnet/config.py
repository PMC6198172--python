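"""Run configuration: every tunable of the inference pipeline in one place.

All randomness flows from ``master_seed`` (which must be set explicitly —
there is no silent time-based seeding), so a run is a pure function of
(input series, config).  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Settings for gLV interaction inference.

    Parameters
    ----------
    carrying_capacity : float
        Community carrying capacity K, cells (or CFU) per gram.
    master_seed : int
        Seed for all randomness (bootstrap partitions and BIC tie-breaking).
    n_bootstraps : int
        Number of bootstrap rounds of stepwise selection.
    train_fraction : float
        Fraction of time points used for training in each round; the first
        time point is always included because it seeds every simulation.
    confidence : float
        One-sample t-test confidence level; an interaction is significant
        when p < 1 - confidence.
    bic_tie_delta : float
        Candidate additions within this ΔBIC of a round's best are treated
        as ties and one is chosen at random; 0 disables the tie rule.
    bic_allowance : float
        Best-BIC retention band: models with BIC ≤ B* + allowance·|B*| are
        kept (``bic_allowance_mode="relative"``), or BIC ≤ B* + allowance
        (``"absolute"``).
    initial_growth_rate : float
        Starting value for every r_i in the optimizer, 1/day.
    n0_fraction : float
        Initial community size used to seed fitting simulations, as a
        fraction of K: x_i(t0) = P[t0, i] · n0_fraction · K.
    zero_floor : float
        Relative abundances of exactly zero at t0 are floored at this value
        (row renormalized) before seeding a simulation, because zero is
        absorbing in the model.
    rss_floor : float
        RSS values below this are floored before the BIC logarithm.
    min_species_abundance, min_community_size : float
        Biological filtering thresholds (absolute units); 0 disables.
    time_window : tuple or None
        Optional (t_min, t_max) restriction of the input series, days.
    u_convention : str
        What "number of data points" U in the BIC means: "t" (one data point
        = one observed composition, i.e. U = number of time points; default)
        or "tn" (time points × taxa, matching the double sum in the RSS).
        The default is the stricter convention: with "tn" the per-parameter
        RSS threshold exp(ln(U)/U)-1 becomes so small that noise-fitting
        coefficients routinely enter the ensemble and the procedure loses
        type-I control on interaction-free data.
    include_unselected_zeros : bool
        Whether coefficients absent from a retained model enter the t-test
        sample as exact zeros (default) or are omitted.
    fit_initial_state : bool
        Whether the initial composition is estimated as n-1 additional free
        parameters (counted in V), initialized at the observed t0 row
        (default), rather than pinned to the observed noisy t0 composition.
        The observed t0 value is measured with the same error as every other
        time point; pinning the simulation to it injects a persistent,
        structured trajectory offset that growth-rate adjustments cannot
        absorb (they change slopes, not intercepts) and that spurious
        interaction coefficients then harvest.
    """

    carrying_capacity: float
    master_seed: int
    n_bootstraps: int = 1000
    train_fraction: float = 0.8
    confidence: float = 0.95
    bic_tie_delta: float = 2.0
    bic_allowance: float = 0.10
    bic_allowance_mode: str = "relative"
    initial_growth_rate: float = 1.0
    n0_fraction: float = 0.01
    zero_floor: float = 1e-6
    rss_floor: float = 1e-12
    min_species_abundance: float = 0.0
    min_community_size: float = 0.0
    time_window: tuple | None = None
    u_convention: str = "t"
    include_unselected_zeros: bool = True
    fit_initial_state: bool = True
    r_bounds: tuple = (-10.0, 10.0)
    a_bounds: tuple = (-50.0, 50.0)
    max_iterations: int = 200
    opt_tol: float = 1e-7
    stepwise_starts: str = "cold"

    def __post_init__(self):
        if not (self.carrying_capacity > 0):
            raise ValueError("carrying_capacity must be positive")
        if self.master_seed is None:
            raise ValueError("master_seed must be set explicitly")
        if not (0 < self.train_fraction <= 1):
            raise ValueError("train_fraction must be in (0, 1]")
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must be in (0, 1)")
        if not (0 < self.n0_fraction <= 1):
            raise ValueError("n0_fraction must be in (0, 1]")
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be at least 1")
        if self.bic_allowance < 0 or self.bic_tie_delta < 0:
            raise ValueError("bic_allowance and bic_tie_delta must be non-negative")
        if self.bic_allowance_mode not in ("relative", "absolute"):
            raise ValueError("bic_allowance_mode must be 'relative' or 'absolute'")
        if self.u_convention not in ("tn", "t"):
            raise ValueError("u_convention must be 'tn' or 't'")
        if self.stepwise_starts not in ("both", "cold", "warm"):
            raise ValueError("stepwise_starts must be 'both', 'cold' or 'warm'")
        if self.time_window is not None:
            object.__setattr__(self, "time_window", tuple(float(v) for v in self.time_window))
        object.__setattr__(self, "r_bounds", tuple(float(v) for v in self.r_bounds))
        object.__setattr__(self, "a_bounds", tuple(float(v) for v in self.a_bounds))

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("time_window", "r_bounds", "a_bounds"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
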