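"""Model/Results interface to the full inference pipeline.

:class:`GLVInteractionModel` holds the data (one or more relative-abundance
series) and the run configuration; :meth:`~GLVInteractionModel.fit` executes
bagged stepwise selection and returns a :class:`GLVInteractionResults`
carrying the retained ensemble, the aggregated coefficients with their
t-tests, the significant-interaction network, and a ``summary()`` table.

Typical use::

    from glvnet import GLVInteractionModel, RunConfig

    config = RunConfig(carrying_capacity=1e11, master_seed=7, n_bootstraps=200)
    model = GLVInteractionModel.from_dataframe(df, config, values="counts")
    results = model.fit()
    print(results.summary())
    results.save("out/")
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bagging import (
    ModelEnsemble,
    aggregate_and_test,
    filter_models,
    run_bagging,
    select_best,
)
from .config import RunConfig
from .data_io import apply_time_window, read_abundance_table
from .dynamics import AbundanceSeries
from .network import InteractionNetwork, build_network

__all__ = ["GLVInteractionModel", "GLVInteractionResults"]


class GLVInteractionModel:
    """Generalized Lotka-Volterra interaction inference from compositional data.

    Parameters
    ----------
    series : AbundanceSeries or sequence of AbundanceSeries
        The observed relative-abundance time series; a sequence is treated
        as per-subject replicates sharing the same taxa (each bootstrap
        round then draws one subject).
    config : RunConfig
        All pipeline settings, including carrying capacity and master seed.
        A ``time_window`` in the config is applied on construction.
    """

    def __init__(self, series, config: RunConfig):
        if isinstance(series, AbundanceSeries):
            series_list = [series]
        else:
            series_list = list(series)
            if not series_list:
                raise ValueError("no input series")
            taxa = series_list[0].taxa
            if any(s.taxa != taxa for s in series_list):
                raise ValueError("all series must share the same taxa in the same order")
        if config.time_window is not None:
            series_list = [apply_time_window(s, config.time_window) for s in series_list]
        self.series_list = series_list
        self.config = config

    @property
    def series(self) -> AbundanceSeries:
        """The (first) input series."""
        return self.series_list[0]

    @property
    def taxa(self) -> tuple:
        return self.series_list[0].taxa

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: RunConfig, values: str = "relative"):
        """Build from a taxa-by-time DataFrame (columns = times in days)."""
        import io as _io

        buf = _io.StringIO()
        df2 = df.copy()
        df2.index.name = df2.index.name or "taxon"
        df2.to_csv(buf, sep="\t")
        buf.seek(0)
        return cls(read_abundance_table(buf, values=values, sep="\t"), config)

    @classmethod
    def from_table(cls, path, config: RunConfig, values: str = "counts"):
        return cls(read_abundance_table(path, values=values), config)

    def fit(self, n_bootstraps: int | None = None, threads: int = 1) -> "GLVInteractionResults":
        """Run bagged stepwise selection and aggregate the retained models.

        Stages: bootstrap rounds of (partition → forward stepwise selection),
        biological filtering, minimum-BIC + allowance retention, coefficient
        aggregation with one-sample t-tests, and network construction.
        """
        cfg = self.config
        data = self.series_list[0] if len(self.series_list) == 1 else self.series_list
        raw = run_bagging(data, cfg, n_bootstraps=n_bootstraps, threads=threads)
        filtered = filter_models(raw, cfg, self.series_list[0])
        retained = select_best(filtered, cfg.bic_allowance, cfg.bic_allowance_mode)
        coefficients, growth = aggregate_and_test(
            retained, cfg.confidence, cfg.include_unselected_zeros
        )
        network = build_network(coefficients, growth, self.taxa)
        return GLVInteractionResults(
            model=self,
            ensemble=raw,
            filtered=filtered,
            retained=retained,
            coefficients=coefficients,
            growth=growth,
            network=network,
        )


@dataclass
class GLVInteractionResults:
    """Fitted results: ensembles, aggregated coefficients, and the network."""

    model: GLVInteractionModel
    ensemble: ModelEnsemble
    filtered: ModelEnsemble
    retained: ModelEnsemble
    coefficients: list
    growth: dict
    network: InteractionNetwork

    @property
    def taxa(self) -> tuple:
        return self.model.taxa

    @property
    def significant(self) -> list:
        return [c for c in self.coefficients if c.significant]

    def coefficients_dataframe(self) -> pd.DataFrame:
        """All ordered pairs with aggregation statistics (significant or not)."""
        taxa = self.taxa
        rows = [
            {
                "source": taxa[c.pair[1]],
                "target": taxa[c.pair[0]],
                "coefficient_mean": c.mean,
                "t_statistic": c.t_statistic,
                "p_value": c.p_value,
                "selection_frequency": c.selection_frequency,
                "significant": c.significant,
            }
            for c in self.coefficients
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["source", "target"])
            .reset_index(drop=True)
        )

    def growth_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"taxon": t, "growth_rate_mean": m, "growth_rate_se": se}
                for t, (m, se) in self.growth.items()
            ]
        )

    def summary(self) -> str:
        """Human-readable report of the fit."""
        cfg = self.model.config
        lines = []
        w = 78
        lines.append("gLV Interaction Inference Results".center(w))
        lines.append("=" * w)
        lines.append(
            f"Taxa: {len(self.taxa)}    Time points: {self.model.series.n_times}"
            f"    Bootstraps: {self.ensemble.n_requested}"
            f" (failed: {self.ensemble.n_failed},"
            f" filtered: {len(self.filtered.filter_log)})"
        )
        lines.append(
            f"Retained models (min BIC + {cfg.bic_allowance:g} allowance,"
            f" {cfg.bic_allowance_mode}): {len(self.retained)}"
            f"    min BIC: {self.retained.bics.min():.2f}"
        )
        lines.append(
            f"Carrying capacity: {cfg.carrying_capacity:g}    "
            f"train fraction: {cfg.train_fraction:g}    seed: {cfg.master_seed}"
        )
        lines.append("-" * w)
        lines.append("Intrinsic growth rates (mean ± SE over retained models, 1/day)")
        for t, (m, se) in self.growth.items():
            lines.append(f"  {t:<24s} {m:8.4f} ± {se:.4f}")
        lines.append("-" * w)
        sig = self.significant
        lines.append(
            f"Significant interactions (one-sample t-test, p < {1 - cfg.confidence:g}): {len(sig)}"
        )
        if sig:
            lines.append(
                f"  {'source':<16s}{'target':<16s}{'a_ij':>10s}{'p':>12s}{'freq':>8s}"
            )
            taxa = self.taxa
            for c in sorted(sig, key=lambda c: c.p_value):
                lines.append(
                    f"  {taxa[c.pair[1]]:<16s}{taxa[c.pair[0]]:<16s}"
                    f"{c.mean:>10.4f}{c.p_value:>12.3e}{c.selection_frequency:>8.2f}"
                )
        lines.append("-" * w)
        lines.append("Ecological pair classification")
        for (a, b), lab in sorted(self.network.pair_labels.items()):
            lines.append(f"  {a} ~ {b}: {lab}")
        lines.append("=" * w)
        lines.append("Edge direction: source j -> target i encodes a_ij (effect of j on i).")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed compositions (points) vs the best retained model (curves).

        Returns the matplotlib Axes.  Uses the minimum-BIC retained model,
        simulated from its fitted initial state over a dense time grid.
        """
        import matplotlib.pyplot as plt
        import numpy as np

        from .dynamics import simulate, to_relative
        from .fitting import _seed_state

        cfg = self.model.config
        series = self.model.series
        best = min(self.retained.models, key=lambda m: m.bic_full)
        if best.p0 is not None:
            y0 = np.asarray(best.p0) * cfg.n0_fraction
        else:
            y0 = _seed_state(series.P[0], cfg)
        dense = np.linspace(series.times[0], series.times[-1], 200)
        pred = to_relative(simulate(best.params, y0 * cfg.carrying_capacity, dense))

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
        for i, taxon in enumerate(series.taxa):
            c = colors[i % len(colors)]
            ax.plot(series.times, series.P[:, i], "o", ms=4, color=c, label=taxon)
            ax.plot(dense, pred.P[:, i], "-", color=c)
        ax.set_xlabel("time (days)")
        ax.set_ylabel("relative abundance")
        ax.set_ylim(0, 1)
        ax.legend(frameon=False, fontsize=8)
        ax.set_title("observed (points) vs best retained gLV model (curves)")
        return ax

    def save(self, out_dir) -> None:
        """Write edges/nodes TSVs, GraphML, the full aggregation JSON and config."""
        import json
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.network.write_edges_tsv(os.path.join(out_dir, "edges.tsv"))
        self.network.write_nodes_tsv(os.path.join(out_dir, "nodes.tsv"))
        self.network.write_graphml(os.path.join(out_dir, "network.graphml"))
        taxa = self.taxa
        audit = {
            "direction_convention": "edge j->i encodes a_ij (effect of j on i)",
            "n_requested": self.ensemble.n_requested,
            "n_failed": self.ensemble.n_failed,
            "n_filtered": len(self.filtered.filter_log),
            "n_retained": len(self.retained),
            "growth_rates": {
                t: {"mean": m, "se": se} for t, (m, se) in self.growth.items()
            },
            "coefficients": [
                {
                    "source": taxa[c.pair[1]],
                    "target": taxa[c.pair[0]],
                    "mean": c.mean,
                    "t_statistic": c.t_statistic,
                    "p_value": c.p_value,
                    "selection_frequency": c.selection_frequency,
                    "significant": c.significant,
                }
                for c in self.coefficients
            ],
        }
        with open(os.path.join(out_dir, "aggregation.json"), "w") as fh:
            json.dump(audit, fh, indent=2)
        self.model.config.to_yaml(os.path.join(out_dir, "resolved_config.yaml"))
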