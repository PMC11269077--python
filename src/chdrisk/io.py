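"""Procedure-outcome tables: loading, validation, and cohort inclusion rules.

The central input is a *procedure-outcome table*: one row per surgical
procedure with its case count ``cases`` (n_j) and in-hospital death count
``deaths`` (d_j), optionally annotated with consensus risk grades
(RACHS-1, 1-6; STS-EACTS, 1-5).  A packaged table transcribed from a
published single-centre pediatric congenital heart surgery cohort
(24,685 operations, 591 in-hospital deaths across 102 procedure types)
ships with the package and drives the worked examples and tests.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of a procedure-outcome table.
PROCEDURE_COLUMNS = ("procedure", "cases", "deaths")
#: Optional ordinal grade columns (consensus risk categories, given as input).
GRADE_COLUMNS = ("rachs_grade", "stseacts_grade")

# Column-name aliases accepted on input files.
_ALIASES = {
    "procedure": ("procedure", "procedure_name", "name"),
    "cases": ("cases", "n", "cases_n"),
    "deaths": ("deaths", "death", "deaths_n", "d"),
}


class ProcedureTableError(ValueError):
    """Raised when a procedure-outcome table violates its invariants."""


def validate_procedure_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate invariants of a procedure-outcome table in place.

    Checks: required columns present, counts are non-negative integers,
    ``0 <= deaths <= cases``, and procedure names are unique.  Returns the
    table unchanged on success.
    """
    for col in PROCEDURE_COLUMNS:
        if col not in table.columns:
            raise ProcedureTableError(f"missing required column {col!r}")
    if len(table) == 0:
        return table
    cases = table["cases"].to_numpy()
    deaths = table["deaths"].to_numpy()
    if not (np.issubdtype(cases.dtype, np.integer) and np.issubdtype(deaths.dtype, np.integer)):
        raise ProcedureTableError("cases and deaths must be integer counts")
    if (cases < 0).any() or (deaths < 0).any():
        raise ProcedureTableError("counts must be non-negative")
    bad = deaths > cases
    if bad.any():
        names = table.loc[bad, "procedure"].tolist()
        raise ProcedureTableError(f"deaths > cases for rows: {names}")
    dup = table["procedure"].duplicated()
    if dup.any():
        names = table.loc[dup, "procedure"].unique().tolist()
        raise ProcedureTableError(f"duplicate procedure names: {names}")
    return table


def load_procedure_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited procedure-outcome table (comma or tab separated).

    The header must contain name/cases/deaths columns (common aliases are
    accepted); optional grade columns pass through.  Row order is
    preserved and all invariants are enforced.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    rename = {}
    for canonical, aliases in _ALIASES.items():
        for alias in aliases:
            if alias in df.columns:
                rename[alias] = canonical
                break
    df = df.rename(columns=rename)
    validate_procedure_table(df)
    if len(df):
        df["cases"] = df["cases"].astype(np.int64)
        df["deaths"] = df["deaths"].astype(np.int64)
    return df


def write_procedure_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated procedure-outcome table as CSV (round-trip safe)."""
    validate_procedure_table(table)
    table.to_csv(path, index=False)


def apply_inclusion_rules(table: pd.DataFrame, min_cases: int = 3) -> pd.DataFrame:
    """Drop procedures performed fewer than ``min_cases`` times.

    Mirrors the cohort inclusion rule that excludes surgical procedures
    performed in less than 3 patients; the number of removed rows is
    logged.
    """
    validate_procedure_table(table)
    kept = table[table["cases"] >= min_cases].reset_index(drop=True)
    removed = len(table) - len(kept)
    if removed:
        logger.info("inclusion rules removed %d of %d procedures (cases < %d)",
                    removed, len(table), min_cases)
    return kept


def deduplicate_patient_records(patients: pd.DataFrame,
                                id_col: str = "patient_id",
                                date_col: str = "surgery_date") -> pd.DataFrame:
    """Keep only the last record per (patient, month).

    Input contract helper for registries where a patient may have several
    surgical records within one month: only the last record counts as the
    index operation, earlier ones are operation history.  Rows must carry a
    sortable date column; ties keep the last row in file order.
    """
    if date_col not in patients.columns:
        return patients
    dates = pd.to_datetime(patients[date_col])
    month = dates.dt.to_period("M")
    order = np.lexsort((np.arange(len(patients)), dates.to_numpy()))
    df = patients.iloc[order]
    df = df.assign(_month=month.iloc[order].to_numpy())
    df = df.drop_duplicates(subset=[id_col, "_month"], keep="last").drop(columns="_month")
    return df.sort_index()


def raw_rate(deaths, cases):
    """Unadjusted mortality ``deaths / cases`` (vectorised).

    Raises for ``cases == 0``: the raw rate of an unperformed procedure is
    undefined.
    """
    deaths = np.asarray(deaths)
    cases = np.asarray(cases)
    if (cases == 0).any():
        raise ZeroDivisionError("raw rate undefined for cases == 0")
    if ((deaths < 0) | (deaths > cases)).any():
        raise ProcedureTableError("need 0 <= deaths <= cases")
    out = deaths / cases
    return float(out) if out.ndim == 0 else out


def format_percent(rate) -> str:
    """Render a proportion as a percentage with two decimals, e.g. '0.29%'."""
    return f"{100 * float(rate):.2f}%"


def load_reference_cohort() -> pd.DataFrame:
    """Packaged procedure-outcome table of the reference cohort (102 rows)."""
    with resources.files("chdrisk.data").joinpath("procedure_outcomes.csv").open() as f:
        return load_procedure_table(f)


def load_reference_stratification() -> pd.DataFrame:
    """Published per-procedure rates and risk categories of the reference cohort.

    Columns: ``procedure``, ``unadjusted_pct`` and ``model_based_pct``
    (percentages as printed in the source report), and the published
    ``risk_category`` (1-5).  Used for cross-checks, never as an input to
    estimation.
    """
    with resources.files("chdrisk.data").joinpath("reported_stratification.csv").open() as f:
        return pd.read_csv(f)
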