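"""Probe-by-sample matrix of normalized log2(MeDIP/input) ratios.

The matrix is the pipeline's main input: rows are array probes, columns
are subjects, and each subject carries a two-group label.  The canonical
labels are ``CPA`` (chronic physical aggression, the case group) and
``control``; arbitrary labels in a design file can be mapped onto them.
Missing values are a hard error — the arrays this models are complete
after upstream normalization, and imputation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GROUP_CASE", "GROUP_CONTROL", "MethylationMatrix", "read_matrix", "write_matrix"]

GROUP_CASE = "CPA"
GROUP_CONTROL = "control"


@dataclass
class MethylationMatrix:
    """Log2 ratio matrix with aligned probe ids and sample group labels."""

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group_labels = [str(g) for g in self.group_labels]
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D probes x samples array")
        n_probes, n_samples = self.values.shape
        if len(self.probe_ids) != n_probes:
            raise ValueError("probe_ids length does not match the number of rows")
        if len(self.sample_ids) != n_samples or len(self.group_labels) != n_samples:
            raise ValueError("sample_ids/group_labels length does not match columns")
        if len(set(self.probe_ids)) != n_probes:
            seen: set[str] = set()
            dup = next(p for p in self.probe_ids if p in seen or seen.add(p))
            raise ValueError(f"duplicated probe_id {dup!r}")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicated sample ids")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite value at probe {self.probe_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        bad_labels = set(self.group_labels) - {GROUP_CASE, GROUP_CONTROL}
        if bad_labels:
            raise ValueError(
                f"group labels must be {{{GROUP_CASE!r}, {GROUP_CONTROL!r}}}, "
                f"got extra {sorted(bad_labels)}"
            )
        for group in (GROUP_CASE, GROUP_CONTROL):
            if sum(g == group for g in self.group_labels) < 2:
                raise ValueError(f"group {group!r} needs at least 2 samples")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.group_labels], dtype=bool)

    def group_counts(self) -> tuple[int, int]:
        """(n_case, n_control)."""
        case = int(self.group_mask(GROUP_CASE).sum())
        return case, self.n_samples - case


def read_matrix(
    matrix_path: str | Path,
    design_path: str | Path,
    group_map: dict[str, str] | None = None,
) -> MethylationMatrix:
    """Read a probe x sample TSV plus a (sample_id, group) design TSV.

    ``group_map`` translates arbitrary design labels onto the canonical
    {CPA, control} vocabulary; by default labels must already be canonical.
    """
    df = pd.read_csv(
        matrix_path, sep="\t", na_values=["NA", "NaN", ""],
        keep_default_na=True, float_precision="round_trip",
    )
    if df.columns[0] != "probe_id":
        raise ValueError(f"matrix {matrix_path}: first column must be 'probe_id'")
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in design.columns:
            raise ValueError(f"design {design_path} lacks column {col!r}")
    probe_ids = df["probe_id"].astype(str).tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    if df[df.columns[1:]].isna().any().any():
        row, col = next(
            (r, c) for c in df.columns[1:] for r in df.index[df[c].isna()]
        )
        raise ValueError(
            f"matrix {matrix_path}: missing value at probe {probe_ids[row]!r}, sample {col!r}"
        )
    labels_by_sample = dict(zip(design["sample_id"], design["group"]))
    absent = [s for s in labels_by_sample if s not in sample_ids]
    if absent:
        raise ValueError(f"design samples absent from matrix: {absent}")
    missing = [s for s in sample_ids if s not in labels_by_sample]
    if missing:
        raise ValueError(f"matrix samples absent from design: {missing}")
    labels = [labels_by_sample[s] for s in sample_ids]
    if group_map is not None:
        unknown = [g for g in labels if g not in group_map]
        if unknown:
            raise ValueError(f"design groups not covered by group_map: {sorted(set(unknown))}")
        labels = [group_map[g] for g in labels]
    values = df[df.columns[1:]].to_numpy(dtype=float)
    return MethylationMatrix(values, probe_ids, sample_ids, labels)


def write_matrix(matrix: MethylationMatrix, matrix_path: str | Path,
                 design_path: str | Path, float_format: str = "%.17g") -> None:
    """Write the matrix and its design file in `read_matrix` format."""
    df = pd.DataFrame(matrix.values, columns=matrix.sample_ids)
    df.insert(0, "probe_id", matrix.probe_ids)
    df.to_csv(matrix_path, sep="\t", index=False, float_format=float_format)
    design = pd.DataFrame({"sample_id": matrix.sample_ids, "group": matrix.group_labels})
    design.to_csv(design_path, sep="\t", index=False)
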