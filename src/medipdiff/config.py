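"""Analysis configuration shared by every pipeline stage.

The defaults encode the calling rules of the study this package
reimplements: a probe is differentially methylated when its moderated-t
p-value is at most 0.05 (uncorrected) and its absolute log2 fold
difference is at least 0.25, and the containing promoter when the
Benjamini-Hochberg FDR of the promoter-level rank-sum statistic is at
most 0.2 (0.05 for the stricter secondary list).  The genome is scanned
for spatial clustering in fixed 500 kb windows.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and tuning knobs for the differential-methylation pipeline.

    Parameters
    ----------
    probe_p_threshold
        Maximum (uncorrected) moderated-t p-value for a probe call.
    min_abs_log2fc
        Minimum absolute log2 fold difference (CPA minus control group
        means) for a probe call.
    promoter_fdr_threshold
        Maximum Benjamini-Hochberg FDR of the promoter rank-sum statistic
        for a differential-methylation call.
    strict_fdr_threshold
        FDR cut-off for the stricter secondary promoter list.
    window_size
        Width in bp of the non-overlapping genomic windows scanned for
        enrichment of differentially methylated probes.
    max_correlation_distance
        Largest probe-pair separation (bp) entering the distance
        correlation analysis.
    distance_bin_width
        Width in bp of the distance bins for pairwise correlations.
    permutations
        Number of within-chromosome position permutations used for the
        null envelope of the distance correlation.
    pair_cap
        Maximum number of probe pairs retained per distance bin
        (uniform seeded subsampling beyond the cap).
    seed
        Seed for every stochastic step (pair subsampling, permutations).
    direction_adjust
        How the two one-sided promoter p-values are combined before FDR:
        ``"pooled"`` takes min(p_up, p_down) as-is, ``"bonferroni"``
        doubles it (capped at 1).
    density_denominator
        Denominator convention for CpG dinucleotide density:
        ``"dinucleotide"`` uses L-1 positions, ``"length"`` uses L.
    """

    probe_p_threshold: float = 0.05
    min_abs_log2fc: float = 0.25
    promoter_fdr_threshold: float = 0.2
    strict_fdr_threshold: float = 0.05
    window_size: int = 500_000
    max_correlation_distance: int = 10_000_000
    distance_bin_width: int = 500_000
    permutations: int = 200
    pair_cap: int = 2_000_000
    seed: int = 0
    direction_adjust: str = "pooled"
    density_denominator: str = "dinucleotide"

    def __post_init__(self) -> None:
        for name in ("probe_p_threshold", "promoter_fdr_threshold", "strict_fdr_threshold"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value!r}")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be non-negative")
        for name in ("window_size", "max_correlation_distance", "distance_bin_width", "pair_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.permutations < 0:
            raise ValueError("permutations must be non-negative")
        if self.direction_adjust not in ("pooled", "bonferroni"):
            raise ValueError("direction_adjust must be 'pooled' or 'bonferroni'")
        if self.density_denominator not in ("dinucleotide", "length"):
            raise ValueError("density_denominator must be 'dinucleotide' or 'length'")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a JSON or YAML mapping of field names."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            payload = json.loads(text)
        else:
            payload = yaml.safe_load(text)
        if payload is None:
            payload = {}
        if not isinstance(payload, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
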