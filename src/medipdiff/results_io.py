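"""Readers/writers for stage result tables with stable column order.

All result files are TSV with a documented header; floats are written
with enough digits to round-trip calls exactly.  Empty result sets
produce a header-only file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "PROBE_RESULT_COLUMNS",
    "PROMOTER_RESULT_COLUMNS",
    "write_results",
    "read_probe_results",
    "read_promoter_results",
]

PROBE_RESULT_COLUMNS = [
    "probe_id", "log2fc", "residual_variance", "residual_df",
    "posterior_variance", "moderated_t", "p_value", "probe_call",
]
PROMOTER_RESULT_COLUMNS = [
    "promoter_id", "n_probes", "p_up", "p_down", "direction",
    "promoter_p", "fdr", "n_called_probes", "dm_call", "strict_call",
]


def write_results(results: pd.DataFrame, path: str | Path,
                  columns: list[str] | None = None) -> None:
    """Write a result table as TSV in a deterministic column order.

    ``columns`` defaults to the probe/promoter schema when the frame
    matches one, otherwise the frame's own order is kept.
    """
    if columns is None:
        for schema in (PROBE_RESULT_COLUMNS, PROMOTER_RESULT_COLUMNS):
            if set(schema) <= set(results.columns):
                columns = schema
                break
        else:
            columns = list(results.columns)
    results[columns].to_csv(path, sep="\t", index=False, float_format="%.12g")


def _read(path: str | Path, columns: list[str], bools: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"result file {path} lacks columns {missing}")
    for col in bools:
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().map({"true": True, "false": False})
    return df[columns]


def read_probe_results(path: str | Path) -> pd.DataFrame:
    return _read(path, PROBE_RESULT_COLUMNS, [])


def read_promoter_results(path: str | Path) -> pd.DataFrame:
    return _read(path, PROMOTER_RESULT_COLUMNS, ["dm_call", "strict_call"])
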