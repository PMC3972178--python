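"""Group-comparison statistics recomputable from printed cohort summaries.

Epidemiological cohort tables report continuous variables as mean +/- SD
with group sizes, and categorical ones as 2x2 counts.  This module
recomputes the comparisons such tables print: a pooled-variance
(Student) two-sample t-test from the summaries alone, and a two-tailed
Fisher exact test from the counts.  The two-tailed Fisher p-value is the
point-probability method — the sum of hypergeometric probabilities of
all tables with the same margins that are no more likely than the
observed one (within a 1 + 1e-7 relative tolerance) — which is the
convention standard statistical software uses.

A transcription of the published CPA-vs-control cohort characteristics
ships as a packaged fixture (``load_reference_cohort``): group a is the
control group (n = 12), group b the chronic-physical-aggression group
(n = 8; n = 7 for variables with missing subjects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryVariable",
    "CountVariable",
    "CohortTable",
    "pooled_t_from_summaries",
    "fisher_exact_2x2",
    "cohort_report",
    "load_cohort_table",
    "load_reference_cohort",
]


@dataclass(frozen=True)
class SummaryVariable:
    """A continuous variable summarised as mean +/- SD (n) per group."""

    name: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError(f"{self.name}: both groups need n >= 2")
        if self.sd_a < 0 or self.sd_b < 0:
            raise ValueError(f"{self.name}: standard deviations must be >= 0")


@dataclass(frozen=True)
class CountVariable:
    """A binary variable summarised as yes/no counts per group."""

    name: str
    a_yes: int
    a_no: int
    b_yes: int
    b_no: int

    def __post_init__(self) -> None:
        counts = (self.a_yes, self.a_no, self.b_yes, self.b_no)
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.name}: counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError(f"{self.name}: empty table")


@dataclass
class CohortTable:
    variables: list[SummaryVariable | CountVariable]


def pooled_t_from_summaries(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from group summaries.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2`` and a two-sided
    p-value from the Student t distribution.  The pooled convention (not
    Welch) is what cohort tables printing t(df) with df = n_a+n_b-2 use.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need n >= 2")
    if sd_a == 0 and sd_b == 0:
        raise ValueError("pooled t undefined when both SDs are zero")
    df = n_a + n_b - 2
    pooled = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    t = (mean_a - mean_b) / math.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return t, df, p


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-tailed Fisher exact test on the table [[a, b], [c, d]].

    Returns the sample odds ratio ``ad/bc`` (inf when ``bc = 0`` with
    ``ad > 0``, nan for 0/0) and the point-probability two-tailed
    p-value.
    """
    for value in (a, b, c, d):
        if not float(value).is_integer() or value < 0:
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def cohort_report(table: CohortTable) -> pd.DataFrame:
    """Apply the appropriate test to every variable of a cohort table.

    Summary variables get the pooled t-test, count variables the
    two-tailed Fisher exact test.  Invalid rows are flagged in an
    ``error`` column without aborting the rest of the table.
    """
    rows = []
    for var in table.variables:
        row: dict = {"name": var.name, "error": ""}
        try:
            if isinstance(var, SummaryVariable):
                t, df, p = pooled_t_from_summaries(
                    var.mean_a, var.sd_a, var.n_a, var.mean_b, var.sd_b, var.n_b
                )
                row.update(test="pooled_t", statistic=t, df=df, p_value=p)
            else:
                odds, p = fisher_exact_2x2(var.a_yes, var.a_no, var.b_yes, var.b_no)
                row.update(test="fisher_exact", statistic=odds, df=np.nan, p_value=p)
        except ValueError as exc:
            row.update(test="", statistic=np.nan, df=np.nan, p_value=np.nan,
                       error=str(exc))
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["name", "test", "statistic", "df", "p_value", "error"]
    )


def _parse_row(row: pd.Series) -> SummaryVariable | CountVariable:
    if row["kind"] == "summary":
        return SummaryVariable(
            row["name"],
            float(row["mean_a"]), float(row["sd_a"]), int(row["n_a"]),
            float(row["mean_b"]), float(row["sd_b"]), int(row["n_b"]),
        )
    if row["kind"] == "count":
        return CountVariable(
            row["name"],
            int(row["a_yes"]), int(row["a_no"]),
            int(row["b_yes"]), int(row["b_no"]),
        )
    raise ValueError(f"unknown variable kind {row['kind']!r}")


def load_cohort_table(path: str | Path) -> CohortTable:
    """Read a cohort TSV with a ``kind`` column (``summary`` or ``count``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "kind"}
    if not required <= set(df.columns):
        raise ValueError(f"cohort table {path} must have columns {sorted(required)}")
    return CohortTable([_parse_row(row) for _, row in df.iterrows()])


def load_reference_cohort() -> CohortTable:
    """The packaged transcription of the published cohort characteristics."""
    with resources.as_file(
        resources.files("medipdiff.data") / "cohort_summary.tsv"
    ) as path:
        return load_cohort_table(path)
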