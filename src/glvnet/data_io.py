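"""Reading and writing longitudinal abundance tables.

The canonical table layout is taxa-by-time delimited text: first column =
taxon identifier, header row = sampling times in days, cells = counts (or
cell densities) or relative abundances.  Counts are converted to composition
by column normalization on load.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dynamics import AbundanceSeries

__all__ = ["read_abundance_table", "write_abundance_table", "apply_time_window", "pool_series"]


def read_abundance_table(path, values: str = "counts", sep: str | None = None) -> AbundanceSeries:
    """Load a taxa-by-time abundance table into an :class:`AbundanceSeries`.

    Parameters
    ----------
    path : str or file-like
        Delimited text table; rows = taxa, columns = time points, first
        column = taxon ID, header row = times in days.
    values : {"counts", "relative"}
        "counts" normalizes each column to sum to 1; "relative" expects
        columns already summing to 1 and renormalizes (with a warning) if
        any column sum is off by more than 1e-6.
    sep : str, optional
        Field delimiter; autodetected (TSV/CSV) when omitted.
    """
    if values not in ("counts", "relative"):
        raise ValueError("values must be 'counts' or 'relative'")
    # header=None: pandas would silently mangle duplicate time columns
    df = pd.read_csv(
        path, sep=sep, engine="python" if sep is None else "c", header=None, dtype=str
    )
    header, df = df.iloc[0, 1:], df.iloc[1:]
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon IDs: {dups}")
    try:
        times = header.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"header row must hold numeric times in days: {exc}") from None
    if np.unique(times).size != times.size:
        raise ValueError("duplicate time points in header row")
    df.columns = range(times.size)

    mat = np.empty((df.shape[0], df.shape[1]))
    for ci, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric value at taxon {row!r}, time column {col!r}")
        mat[:, ci] = converted.to_numpy()
    if (mat < 0).any():
        ti, ci = np.argwhere(mat < 0)[0]
        raise ValueError(
            f"negative value at taxon {df.index[ti]!r}, time column {df.columns[ci]!r}"
        )

    order = np.argsort(times)
    times = times[order]
    mat = mat[:, order]

    sums = mat.sum(axis=0)
    if np.any(sums <= 0):
        ci = int(np.argwhere(sums <= 0)[0])
        raise ValueError(f"time column {times[ci]!r} sums to zero")
    if values == "relative" and np.any(np.abs(sums - 1.0) > 1e-6):
        warnings.warn(
            "relative-abundance columns do not sum to 1; renormalizing",
            UserWarning,
            stacklevel=2,
        )
    P = (mat / sums).T  # times x taxa
    return AbundanceSeries(tuple(df.index.astype(str)), times, P)


def write_abundance_table(series: AbundanceSeries, path, sep: str = "\t") -> None:
    """Write a series back to the canonical taxa-by-time layout."""
    df = pd.DataFrame(
        series.P.T, index=list(series.taxa), columns=[f"{t:g}" for t in series.times]
    )
    df.index.name = "taxon"
    df.to_csv(path, sep=sep)


def apply_time_window(series: AbundanceSeries, window) -> AbundanceSeries:
    """Restrict a series to time points inside [t_min, t_max] (inclusive).

    Used for staged analyses such as age windows 0-365, 0-730, 0-1095 days.
    Requires at least 3 surviving points (the pipeline cannot partition
    fewer).
    """
    t_min, t_max = float(window[0]), float(window[1])
    keep = np.flatnonzero((series.times >= t_min) & (series.times <= t_max))
    if keep.size < 3:
        raise ValueError(
            f"time window [{t_min:g}, {t_max:g}] keeps {keep.size} point(s); need at least 3"
        )
    return series.subset(keep)


def pool_series(series_list, decimals: int = 6) -> AbundanceSeries:
    """Average composition across subjects on the union time grid.

    Each time point's composition is the mean of the compositions of the
    subjects observed at that time (times rounded to ``decimals`` before
    matching).  This is the "mean composition" way of combining per-subject
    series into a single community trajectory; the alternative — bootstrap
    over subjects — is handled by the model layer.
    """
    if not series_list:
        raise ValueError("no series to pool")
    taxa = series_list[0].taxa
    if any(s.taxa != taxa for s in series_list):
        raise ValueError("all series must share the same taxa in the same order")
    grid = sorted({round(float(t), decimals) for s in series_list for t in s.times})
    rows = []
    for t in grid:
        ps = [
            s.P[k]
            for s in series_list
            for k in np.flatnonzero(np.round(s.times, decimals) == t)
        ]
        rows.append(np.mean(ps, axis=0))
    P = np.stack(rows)
    P = P / P.sum(axis=1, keepdims=True)
    return AbundanceSeries(taxa, np.array(grid), P)
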