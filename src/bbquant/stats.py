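"""Group statistics, frequency tabulation and supplementary-table recomputation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyInputError, MappingError

#: Significance star coding: thresholds map p-values to the printed symbols.
STAR_CUTPOINTS = ((1e-4, "****"), (1e-2, "**"), (5e-2, "*"))


def star_code(p_value: float) -> str:
    for cut, stars in STAR_CUTPOINTS:
        if p_value < cut:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    """Two-sample comparison of per-unit values (e.g. fold enrichments)."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    welch: bool = False

    @property
    def stars(self) -> str:
        return star_code(self.p_value)


def sem(values) -> float:
    """Standard error of the mean, SD / sqrt(n) with the n-1 sample SD."""
    values = np.asarray(values, dtype=float)
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def compare_groups(values_a, values_b, welch: bool = False) -> GroupComparison:
    """Two-tailed unpaired t test between two collections of per-unit values.

    Equal-variance Student's t by default; set ``welch=True`` for the
    unequal-variance form.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise EmptyInputError("each group needs at least 2 finite values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain only finite values")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=sem(a),
        sem_b=sem(b),
        t_statistic=float(t),
        p_value=float(p),
        n_a=len(a),
        n_b=len(b),
        welch=welch,
    )


@dataclass
class FrequencyTable:
    """Per-group category counts and percentages, with replicate breakdown."""

    counts: pd.DataFrame  # index = group, columns = categories
    percentages: pd.DataFrame
    by_replicate: pd.DataFrame | None = None


def tabulate_frequencies(
    annotations: pd.DataFrame,
    categories: list[str],
    group_column: str = "group",
    category_column: str = "category",
    replicate_column: str | None = None,
) -> FrequencyTable:
    """Counts and percentages of category labels per group.

    ``annotations`` holds one row per scored unit.  Labels outside the
    declared category set raise; empty groups raise.
    """
    if annotations.empty:
        raise EmptyInputError("no annotations to tabulate")
    unknown = set(annotations[category_column]) - set(categories)
    if unknown:
        raise ValueError(f"unknown category label(s): {sorted(unknown)}")
    counts = (
        annotations.groupby([group_column, category_column])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=categories, fill_value=0)
    )
    if (counts.sum(axis=1) == 0).any():
        raise EmptyInputError("a group has no scored units")
    percentages = counts.div(counts.sum(axis=1), axis=0) * 100.0
    by_rep = None
    if replicate_column is not None:
        by_rep = (
            annotations.groupby([group_column, replicate_column, category_column])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=categories, fill_value=0)
        )
    return FrequencyTable(counts=counts, percentages=percentages, by_replicate=by_rep)


def recompute_supplementary(workbook_path, mapping: dict) -> pd.DataFrame:
    """Recompute group summaries from a per-unit spreadsheet.

    ``mapping`` pins down the sheet layout explicitly (no guessing):

    - ``sheet``: sheet name
    - ``value_columns``: per-unit numeric columns to summarize
    - ``group_column`` (optional): column holding group labels
    - ``header_row`` (optional, default 0): row index of the header

    Returns one row per (group, value column) with n, mean and SEM.
    """
    for key in ("sheet", "value_columns"):
        if key not in mapping:
            raise MappingError(f"mapping stanza missing required key {key!r}")
    try:
        frame = pd.read_excel(
            workbook_path,
            sheet_name=mapping["sheet"],
            header=mapping.get("header_row", 0),
        )
    except ValueError as exc:
        raise MappingError(f"cannot read sheet {mapping['sheet']!r}: {exc}") from exc
    missing = [c for c in mapping["value_columns"] if c not in frame.columns]
    group_col = mapping.get("group_column")
    if group_col is not None and group_col not in frame.columns:
        missing.append(group_col)
    if missing:
        raise MappingError(
            f"sheet {mapping['sheet']!r} lacks mapped column(s) {missing}; "
            f"available: {list(frame.columns)}"
        )

    rows = []
    groups = frame.groupby(group_col) if group_col else [("all", frame)]
    for gname, gframe in groups:
        for col in mapping["value_columns"]:
            vals = pd.to_numeric(gframe[col], errors="coerce").dropna()
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "group": gname,
                    "measure": col,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "sem": sem(vals) if len(vals) > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["group", "measure", "n", "mean", "sem"])
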