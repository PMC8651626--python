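"""Relative read abundances and their regression against microscope counts."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionFit",
    "to_rra",
    "map_to_morphotypes",
    "least_squares_fit",
    "microscope_relative_abundance",
    "quantification_report",
]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def to_rra(table: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative read abundances.

    Counts of the surviving PCR replicates of each sample (role
    ``sample`` only) are averaged per taxon and divided by the sample's
    total mean count.  Samples with zero total are dropped with a
    warning.  Rows are samples, columns taxa; rows sum to 1.
    """
    roles = sheet.set_index("occurrence_id")["role"]
    sample_map = sheet.set_index("occurrence_id")["sample_id"]
    cols = [c for c in table.columns if roles.get(c) == "sample"]
    if not cols:
        raise ValueError("no sample occurrences in table")
    means: dict[str, pd.Series] = {}
    by_sample: dict[str, list[str]] = {}
    for c in cols:
        by_sample.setdefault(sample_map[c], []).append(c)
    for sid, occs in by_sample.items():
        means[sid] = table[occs].mean(axis=1)
    rra = pd.DataFrame(means).T
    rra.index.name = "sample_id"
    totals = rra.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"dropping zero-total samples: {empty}")
        rra = rra.drop(index=empty)
        totals = totals.drop(index=empty)
    return rra.div(totals, axis=0)


def map_to_morphotypes(
    rra: pd.DataFrame, morphotype_map: Mapping[str, str]
) -> pd.DataFrame:
    """Sum taxon columns within morphotypes; row sums are preserved.

    The map must be total over the table's columns; unmapped taxa are an
    error (map explicitly to ``"other"`` to pool leftovers).
    """
    missing = [c for c in rra.columns if c not in morphotype_map]
    if missing:
        raise KeyError(f"morphotype map missing taxa: {missing[:5]}")
    grouped = rra.T.groupby(
        rra.columns.map(morphotype_map)
    ).sum().T
    grouped.columns.name = None
    return grouped


def least_squares_fit(x, y) -> RegressionFit:
    """Ordinary least squares of ``y`` on ``x`` with the slope's t-test
    p-value at n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x: slope undefined")
    res = stats.linregress(x, y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    resid = y - (res.intercept + res.slope * x)
    ss_res = float((resid**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def microscope_relative_abundance(microscope: pd.DataFrame) -> pd.DataFrame:
    """Convert pollen/m3 concentrations to within-sample relative
    abundances over all counted morphotypes."""
    totals = microscope.sum(axis=1)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"samples with zero pollen counted: {bad[:5]}")
    return microscope.div(totals, axis=0)


def quantification_report(
    rra_by_marker: Mapping[str, pd.DataFrame],
    microscope: pd.DataFrame,
    morphotype_map: Mapping[str, str],
    target_morphotypes: list[str] | tuple[str, ...],
    combined_min_frac: float = 0.05,
) -> pd.DataFrame:
    """Per-target and combined regressions of RRA on microscope
    relative abundance, one row per (marker, target).

    The combined fit pools every (sample, morphotype) point whose
    microscope relative abundance exceeds ``combined_min_frac``.
    """
    micro_rel = microscope_relative_abundance(microscope)
    rows = []
    for marker, rra in rra_by_marker.items():
        morpho = map_to_morphotypes(rra, morphotype_map)
        shared = morpho.index.intersection(micro_rel.index)
        if len(shared) == 0:
            raise ValueError(f"no shared samples for marker {marker!r}")
        common_taxa = [m for m in micro_rel.columns if m in morpho.columns]

        for target in target_morphotypes:
            if target not in common_taxa:
                continue
            x = micro_rel.loc[shared, target].to_numpy()
            y = morpho.loc[shared, target].to_numpy()
            if x.size < 3 or np.allclose(x, x[0]):
                continue
            fit = least_squares_fit(x, y)
            rows.append({"marker": marker, "target": target, **fit.__dict__})

        xs, ys = [], []
        for m in common_taxa:
            x = micro_rel.loc[shared, m].to_numpy()
            y = morpho.loc[shared, m].to_numpy()
            keep = x > combined_min_frac
            xs.append(x[keep])
            ys.append(y[keep])
        x_all = np.concatenate(xs) if xs else np.array([])
        y_all = np.concatenate(ys) if ys else np.array([])
        if x_all.size >= 3 and not np.allclose(x_all, x_all[0]):
            fit = least_squares_fit(x_all, y_all)
            rows.append({"marker": marker, "target": "combined", **fit.__dict__})
    return pd.DataFrame(
        rows,
        columns=["marker", "target", "slope", "intercept", "r_squared",
                 "p_value", "n"],
    )
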