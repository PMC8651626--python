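"""Six-step contamination filter cascade with a data-driven leakage threshold.

Steps, in order: (a) drop OTUs more abundant in blanks than in samples;
(b) zero per-replicate counts below a minimum; (c) solve and apply the
leakage threshold that zeroes every blank count; (d) drop low-depth
replicates (and samples with none left); (e) drop off-target clades and
listed contaminant taxa; (f) require presence in >= 2 PCR replicates of
a sample.  A per-step report records removals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FilterParams",
    "FilterStep",
    "FilterReport",
    "remove_blank_dominant",
    "solve_leakage_threshold",
    "apply_leakage_threshold",
    "run_filter_cascade",
    "check_positive_controls",
    "PositiveControlCheck",
]

BLANK_ROLES = ("extraction_blank", "pcr_negative")


@dataclass
class FilterParams:
    min_reads_per_repeat: int = 10
    min_repeat_depth: int = 3000
    min_replicates_present: int = 2
    excluded_clades: tuple[str, ...] = ("fungi", "bryophytes", "green_algae")
    contaminant_taxa: tuple[str, ...] = ()
    # leakage denominator: per-OTU dataset total ("otu_total", tag-jump
    # convention) or the occurrence column total ("occurrence_total")
    leakage_denominator: str = "otu_total"

    def __post_init__(self) -> None:
        if self.leakage_denominator not in ("otu_total", "occurrence_total"):
            raise ValueError(
                f"unknown leakage denominator {self.leakage_denominator!r}"
            )


@dataclass
class FilterStep:
    label: str
    otus_removed: int = 0
    reads_removed: int = 0
    replicates_removed: int = 0
    samples_removed: int = 0
    parameters: dict = dc_field(default_factory=dict)


@dataclass
class FilterReport:
    steps: list[FilterStep] = dc_field(default_factory=list)
    single_replicate_samples: list[str] = dc_field(default_factory=list)
    leakage_threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.label,
                    "otus_removed": s.otus_removed,
                    "reads_removed": s.reads_removed,
                    "replicates_removed": s.replicates_removed,
                    "samples_removed": s.samples_removed,
                    "parameters": ";".join(
                        f"{k}={v}" for k, v in s.parameters.items()
                    ),
                }
                for s in self.steps
            ]
        )


def _roles(sheet: pd.DataFrame) -> pd.Series:
    return sheet.set_index("occurrence_id")["role"]


def _blank_cols(table: pd.DataFrame, roles: pd.Series) -> list[str]:
    return [c for c in table.columns if roles.get(c) in BLANK_ROLES]


def _sample_cols(table: pd.DataFrame, roles: pd.Series) -> list[str]:
    return [c for c in table.columns if roles.get(c) == "sample"]


def remove_blank_dominant(
    table: pd.DataFrame, sheet: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Drop OTUs whose maximum blank/negative count strictly exceeds
    their maximum count in any sample occurrence.  Ties keep the OTU."""
    roles = _roles(sheet)
    blanks = _blank_cols(table, roles)
    samples = _sample_cols(table, roles)
    if not blanks:
        warnings.warn("no blank/negative occurrences; nothing to remove")
        return table.copy(), []
    blank_max = table[blanks].max(axis=1)
    sample_max = (
        table[samples].max(axis=1) if samples else pd.Series(0, index=table.index)
    )
    removed = table.index[blank_max > sample_max].tolist()
    return table.drop(index=removed), removed


def solve_leakage_threshold(
    table: pd.DataFrame,
    sheet: pd.DataFrame,
    denominator: str = "otu_total",
) -> float:
    """Smallest threshold ``t`` such that zeroing every count
    ``c <= t * T`` empties all blank/negative occurrences.

    With the per-OTU convention, ``T`` is the OTU's total reads across
    the dataset; the minimal sufficient ``t`` is therefore the maximum
    observed blank ratio ``c / T``.  Returns 0 when blanks are empty.
    """
    roles = _roles(sheet)
    blanks = _blank_cols(table, roles)
    if not blanks:
        raise ValueError("table has no blank/negative occurrences")
    ratios = _leak_ratios(table, denominator)
    blank_ratios = ratios[blanks].to_numpy()
    if blank_ratios.size == 0 or blank_ratios.max() == 0:
        return 0.0
    full = blank_ratios >= 1.0 - 1e-12
    if full.any():
        warnings.warn(
            "OTU(s) with all reads in blanks; threshold would zero them "
            "entirely (run blank-dominance removal first)"
        )
    return float(blank_ratios.max())


def _leak_ratios(table: pd.DataFrame, denominator: str) -> pd.DataFrame:
    if denominator == "otu_total":
        totals = table.sum(axis=1).to_numpy()[:, None]
    elif denominator == "occurrence_total":
        totals = table.sum(axis=0).to_numpy()[None, :]
    else:
        raise ValueError(f"unknown leakage denominator {denominator!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(totals > 0, table.to_numpy() / totals, 0.0)
    return pd.DataFrame(ratios, index=table.index, columns=table.columns)


def apply_leakage_threshold(
    table: pd.DataFrame, threshold: float, denominator: str = "otu_total"
) -> pd.DataFrame:
    """Zero every count whose leak ratio is <= ``threshold``."""
    if threshold <= 0:
        return table.copy()
    ratios = _leak_ratios(table, denominator)
    out = table.copy()
    out[(ratios <= threshold) & (out > 0)] = 0
    return out


def run_filter_cascade(
    table: pd.DataFrame,
    sheet: pd.DataFrame,
    row_meta: pd.DataFrame | None = None,
    params: FilterParams | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply filter steps (a)-(f) in order and report per-step removals.

    ``row_meta`` (indexed like ``table``; columns ``clade`` and the
    lineage names) drives step (e); without it that step is skipped
    unless the parameter lists are empty.
    """
    params = params or FilterParams()
    report = FilterReport()
    table = table.copy()
    roles = _roles(sheet)

    def record(label: str, before: pd.DataFrame, after: pd.DataFrame, **extra):
        step = FilterStep(
            label=label,
            otus_removed=len(before.index) - len(after.index),
            reads_removed=int(before.sum().sum() - after.sum().sum()),
            replicates_removed=len(before.columns) - len(after.columns),
            parameters=extra,
        )
        report.steps.append(step)
        return step

    # (a) blank-dominant OTUs
    before = table
    table, removed = remove_blank_dominant(table, sheet)
    record("a_blank_dominant", before, table, removed=len(removed))

    # (b) per-replicate low counts
    before = table
    table = table.where(table >= params.min_reads_per_repeat, 0)
    record(
        "b_min_reads_per_repeat",
        before,
        table,
        min_reads=params.min_reads_per_repeat,
    )

    # (c) leakage threshold
    before = table
    blanks = _blank_cols(table, roles)
    if blanks:
        t_star = solve_leakage_threshold(table, sheet, params.leakage_denominator)
        table = apply_leakage_threshold(table, t_star, params.leakage_denominator)
    else:
        t_star = 0.0
    report.leakage_threshold = t_star
    record("c_leakage", before, table, threshold=t_star)

    # (d) low-depth replicates; a sample is dropped when none survive
    before = table
    sample_cols = _sample_cols(table, roles)
    depths = table[sample_cols].sum(axis=0)
    dropped_cols = [c for c in sample_cols if depths[c] < params.min_repeat_depth]
    table = table.drop(columns=dropped_cols)
    sheet_kept = sheet[sheet.occurrence_id.isin(table.columns)]
    samples_before = sheet.loc[sheet.role == "sample", "sample_id"].nunique()
    samples_after = sheet_kept.loc[
        sheet_kept.role == "sample", "sample_id"
    ].nunique()
    step = record(
        "d_min_repeat_depth",
        before,
        table,
        min_depth=params.min_repeat_depth,
    )
    step.samples_removed = samples_before - samples_after

    # (e) excluded clades and contaminant taxa
    before = table
    if row_meta is not None:
        meta = row_meta.reindex(table.index)
        bad_clade = meta["clade"].isin(params.excluded_clades).fillna(False)
        contam = pd.Series(False, index=table.index)
        if params.contaminant_taxa:
            names = set(params.contaminant_taxa)
            for col in ("species", "genus", "name"):
                if col in meta.columns:
                    contam |= meta[col].isin(names).fillna(False)
        table = table.loc[~(bad_clade | contam)]
    record(
        "e_clades_and_contaminants",
        before,
        table,
        excluded_clades=",".join(params.excluded_clades),
        contaminants=len(params.contaminant_taxa),
    )

    # (f) replicate-consensus within samples
    before = table
    kept_roles = _roles(sheet_kept)
    by_sample: dict[str, list[str]] = {}
    for occ in _sample_cols(table, kept_roles):
        sid = sheet_kept.set_index("occurrence_id").loc[occ, "sample_id"]
        by_sample.setdefault(sid, []).append(occ)
    table = table.copy()
    for sid, occs in by_sample.items():
        if len(occs) < 2:
            report.single_replicate_samples.append(sid)
            continue
        present = (table[occs] > 0).sum(axis=1)
        mask = present < params.min_replicates_present
        table.loc[mask, occs] = 0
    record(
        "f_replicate_consensus",
        before,
        table,
        min_replicates=params.min_replicates_present,
        skipped_single_replicate=len(report.single_replicate_samples),
    )

    # drop all-zero OTU rows
    before = table
    table = table.loc[table.sum(axis=1) > 0]
    record("g_drop_empty_otus", before, table)

    return table, report


@dataclass
class PositiveControlCheck:
    passed: bool | None
    details: dict = dc_field(default_factory=dict)


def check_positive_controls(
    table: pd.DataFrame,
    sheet: pd.DataFrame,
    control_taxon: str,
    row_meta: pd.DataFrame | None = None,
    leakage_threshold: float | None = None,
    min_dominance: float = 0.5,
) -> PositiveControlCheck:
    """Pass iff the control taxon dominates (> ``min_dominance`` of
    reads) every positive-control occurrence and leaks at most the
    leakage threshold into every other occurrence."""
    roles = _roles(sheet)
    controls = [c for c in table.columns if roles.get(c) == "positive_control"]
    if not controls:
        warnings.warn("no positive-control occurrences; check skipped")
        return PositiveControlCheck(passed=None, details={"reason": "no controls"})

    if row_meta is not None:
        is_control_row = pd.Series(False, index=table.index)
        for col in ("species", "genus", "name"):
            if col in row_meta.columns:
                is_control_row |= (
                    row_meta.reindex(table.index)[col]
                    .eq(control_taxon)
                    .fillna(False)
                )
        control_rows = table.index[is_control_row].tolist()
    else:
        control_rows = [r for r in table.index if control_taxon in str(r)]

    details: dict = {"control_rows": control_rows, "per_control": {}}
    if not control_rows:
        return PositiveControlCheck(passed=False, details=details)

    ok = True
    for occ in controls:
        total = int(table[occ].sum())
        control_reads = int(table.loc[control_rows, occ].sum())
        frac = control_reads / total if total else 0.0
        details["per_control"][occ] = frac
        if frac <= min_dominance:
            ok = False

    if leakage_threshold is None:
        leakage_threshold = solve_leakage_threshold(table, sheet)
    control_total = int(table.loc[control_rows].sum().sum())
    worst = 0.0
    for occ in table.columns:
        if roles.get(occ) == "positive_control":
            continue
        if control_total > 0:
            frac = int(table.loc[control_rows, occ].sum()) / control_total
            worst = max(worst, frac)
    details["max_leak_fraction"] = worst
    details["leakage_threshold"] = leakage_threshold
    if worst > leakage_threshold:
        ok = False
    return PositiveControlCheck(passed=ok, details=details)
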