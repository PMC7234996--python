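"""Cohort assembly and trait stratification.

Builds the per-species trait table by cross-referencing a basal-metabolic-rate
source (species, body mass, BMR in kJ/h) with a maximum-lifespan source
(species, lifespan in years, curator quality label) and a KEAP1-functionality
factor (1 = basal Aves with a functional KEAP1, 0 = Neoaves where KEAP1 lost
NRF2 binding). Mass-specific BMR is the raw ratio BMR / mass; every
downstream statistic is rank-based, so the (unstated) mass unit cancels.

Stratification bins a chosen trait into left-closed right-open intervals with
open-ended first and last bins, and each bin is checked for factor balance
with a Mann-Whitney test on the stratifying trait (non-significance at alpha
is read as "indistinguishable"; that accept-the-null logic is reported, not
hidden).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .npstats import MWResult, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "QUALITY_LABELS",
    "MergeReport",
    "StratumAssignment",
    "normalize_name",
    "merge_sources",
    "filter_quality",
    "assign_strata",
    "check_balance",
    "DEFAULT_LIFESPAN_EDGES",
    "DEFAULT_MSBMR_EDGES",
]

QUALITY_LABELS = ("acceptable", "high", "questionable")

# Bin edges reconstructed from the named groups of the source analysis
# ("<10 years", "10-19.9", ..., ">50 years"; MS-BMR "2-2.9", ..., ">8").
DEFAULT_LIFESPAN_EDGES = (10.0, 20.0, 30.0, 40.0, 50.0)
DEFAULT_MSBMR_EDGES = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


def normalize_name(name: str) -> str:
    """Case-fold a binomial and unify space/underscore separators."""
    return " ".join(str(name).replace("_", " ").casefold().split())


@dataclass
class MergeReport:
    retained: int = 0
    dropped_per_source: dict = field(default_factory=dict)
    input_per_source: dict = field(default_factory=dict)
    rejected_rows: list = field(default_factory=list)
    unmatched_names: dict = field(default_factory=dict)


@dataclass
class StratumAssignment:
    """Bin membership for one stratifying variable."""

    variable: str  # "max_lifespan" | "ms_bmr"
    bin_edges: tuple
    bins: pd.Series  # species name -> bin label
    bin_labels: list  # ascending order, incl. open-ended end bins
    n_excluded: int
    excluded_species: list


def _require_columns(df: pd.DataFrame, cols: Sequence[str], source: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{source} table missing columns: {missing}")


def _check_duplicates(names: pd.Series, source: str) -> None:
    dup = sorted(names[names.duplicated()].unique())
    if dup:
        raise ValueError(f"duplicate species in {source} source: {dup}")


def merge_sources(
    bmr_table: pd.DataFrame,
    lifespan_table: pd.DataFrame,
    factor_table: pd.DataFrame,
    column_map: Optional[dict] = None,
) -> tuple[pd.DataFrame, MergeReport]:
    """Inner-join the three sources on normalized species names.

    ``column_map`` renames source headers to the canonical ones
    (species, mass, bmr / species, lifespan, quality / species, keap1).
    Rows with non-positive mass or BMR are rejected with a log entry.
    Returns the merged species trait table and a merge report with
    per-source retained/dropped counts and unmatched names.
    """
    if column_map:
        bmr_table = bmr_table.rename(columns=column_map)
        lifespan_table = lifespan_table.rename(columns=column_map)
        factor_table = factor_table.rename(columns=column_map)
    _require_columns(bmr_table, ["species", "mass", "bmr"], "BMR")
    _require_columns(lifespan_table, ["species", "lifespan", "quality"], "lifespan")
    _require_columns(factor_table, ["species", "keap1"], "factor")

    report = MergeReport()
    tables = {}
    for source, df, valuecols in (
        ("bmr", bmr_table, ["mass", "bmr"]),
        ("lifespan", lifespan_table, ["lifespan", "quality"]),
        ("factor", factor_table, ["keap1"]),
    ):
        df = df.copy()
        report.input_per_source[source] = len(df)
        df["species"] = df["species"].map(normalize_name)
        _check_duplicates(df["species"], source)
        if source == "bmr":
            bad = (df["mass"] <= 0) | (df["bmr"] <= 0)
            for _, row in df[bad].iterrows():
                logger.warning(
                    "rejecting %s: non-positive mass or BMR", row["species"]
                )
                report.rejected_rows.append(row["species"])
            df = df[~bad]
        tables[source] = df[["species"] + valuecols]

    merged = tables["bmr"].merge(tables["lifespan"], on="species", how="inner")
    merged = merged.merge(tables["factor"], on="species", how="inner")
    kept = set(merged["species"])
    for source, df in tables.items():
        dropped = sorted(set(df["species"]) - kept)
        report.dropped_per_source[source] = (
            report.input_per_source[source] - len(merged)
        )
        report.unmatched_names[source] = dropped
    report.retained = len(merged)

    keap1 = merged["keap1"].astype(int)
    if not keap1.isin([0, 1]).all():
        raise ValueError("keap1 factor must be 0 or 1")
    out = pd.DataFrame(
        {
            "species": merged["species"],
            "body_mass": merged["mass"].astype(float),
            "bmr": merged["bmr"].astype(float),
            "ms_bmr": merged["bmr"].astype(float) / merged["mass"].astype(float),
            "max_lifespan": merged["lifespan"].astype(float),
            "lifespan_quality": merged["quality"],
            "keap1_functional": keap1,
        }
    ).reset_index(drop=True)
    bad_quality = sorted(set(out["lifespan_quality"]) - set(QUALITY_LABELS))
    if bad_quality:
        raise ValueError(f"unknown lifespan quality labels: {bad_quality}")
    return out, report


def filter_quality(
    table: pd.DataFrame, include_questionable: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Optionally drop 'questionable' lifespan records.

    The default keeps them: in the source cohort, questionable records were
    conservative lifespan estimates and were retained to increase sample
    size. Returns the filtered table and the retained fraction per label.
    """
    labels = table["lifespan_quality"]
    unknown = sorted(set(labels) - set(QUALITY_LABELS))
    if unknown:
        raise ValueError(f"unknown lifespan quality labels: {unknown}")
    keep = (
        pd.Series(True, index=table.index)
        if include_questionable
        else labels != "questionable"
    )
    out = table[keep].reset_index(drop=True)
    report = {}
    for lab in QUALITY_LABELS:
        n_in = int((labels == lab).sum())
        n_out = int((out["lifespan_quality"] == lab).sum())
        report[lab] = {"input": n_in, "retained": n_out}
    return out, report


def _bin_label(edges: Sequence[float], i: int) -> str:
    if i == 0:
        return f"<{edges[0]:g}"
    if i == len(edges):
        return f">={edges[-1]:g}"
    return f"[{edges[i - 1]:g},{edges[i]:g})"


def assign_strata(
    table: pd.DataFrame, variable: str, bin_edges: Sequence[float]
) -> StratumAssignment:
    """Bin species on ``variable`` into left-closed right-open intervals.

    Values below the first edge fall into a leading open bin, values at or
    above the last edge into a trailing open bin. Species with the variable
    missing are excluded and counted.
    """
    edges = tuple(float(e) for e in bin_edges)
    if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing, >= 1 edge")
    values = table[variable]
    present = values.notna()
    excluded = sorted(table.loc[~present, "species"])
    idx = np.searchsorted(edges, values[present].to_numpy(), side="right")
    labels = pd.Series(
        [_bin_label(edges, i) for i in idx],
        index=table.loc[present, "species"],
        name="bin",
    )
    return StratumAssignment(
        variable=variable,
        bin_edges=edges,
        bins=labels,
        bin_labels=[_bin_label(edges, i) for i in range(len(edges) + 1)],
        n_excluded=len(excluded),
        excluded_species=excluded,
    )


@dataclass
class BalanceCheck:
    stratum_id: str
    n0: int
    n1: int
    result: Optional[MWResult]  # None when untestable
    testable: bool
    passed: Optional[bool]


def check_balance(
    assignment: StratumAssignment, table: pd.DataFrame, alpha: float = 0.05
) -> dict[str, BalanceCheck]:
    """Mann-Whitney balance check of the stratifying variable per bin.

    Within each bin the stratifying variable is compared between
    keap1_functional = 0 and = 1; a bin passes iff p >= alpha (the two factor
    levels are "indistinguishable" on the variable that defines the bin).
    Bins missing a factor level are flagged untestable, not failed.
    """
    indexed = table.set_index("species")
    out: dict[str, BalanceCheck] = {}
    for label in assignment.bin_labels:
        members = assignment.bins[assignment.bins == label].index
        if len(members) == 0:
            continue
        sub = indexed.loc[members]
        v0 = sub.loc[sub["keap1_functional"] == 0, assignment.variable].to_numpy()
        v1 = sub.loc[sub["keap1_functional"] == 1, assignment.variable].to_numpy()
        if len(v0) == 0 or len(v1) == 0:
            out[label] = BalanceCheck(label, len(v0), len(v1), None, False, None)
            continue
        res = mann_whitney(v0, v1)
        out[label] = BalanceCheck(
            label, len(v0), len(v1), res, True, res.p_two_sided >= alpha
        )
    return out
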