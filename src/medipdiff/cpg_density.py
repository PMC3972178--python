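"""Normalized CpG density of promoters and contrasts between call groups.

Normalized CpG density is the observed CpG dinucleotide density divided
by the density expected from base composition — the product of the C and
G base densities.  Values near 1 indicate CpG-island-like promoters;
bulk genomic DNA sits far below because of CpG depletion.  The
dinucleotide denominator is L-1 (the number of dinucleotide positions);
a plain L denominator is available via
``AnalysisConfig.density_denominator`` and the two agree to <1% for
regions longer than ~1 kb.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .annotation import GenomicAnnotation
from .probe_stats import CALL_DOWN, CALL_UP

__all__ = [
    "normalized_cpg_density",
    "density_from_sequence",
    "annotation_density",
    "compare_density_groups",
]

_VALID_BASES = set("ACGTN")


def normalized_cpg_density(
    cpg_count: int,
    c_count: int,
    g_count: int,
    length_bp: int,
    denominator: str = "dinucleotide",
) -> float:
    """Observed/expected CpG density from counts over a region.

    ``(cpg/(L-1)) / ((c/L) * (g/L))`` with the default dinucleotide
    denominator, or ``cpg/L`` in the numerator with
    ``denominator="length"``.  Returns ``nan`` (undefined) when the
    region contains no C or no G.
    """
    if length_bp < 2:
        raise ValueError("length_bp must be at least 2")
    if cpg_count < 0 or c_count < 0 or g_count < 0:
        raise ValueError("counts must be non-negative")
    if cpg_count > min(c_count, g_count):
        raise ValueError("cpg_count cannot exceed min(c_count, g_count)")
    if c_count == 0 or g_count == 0:
        return math.nan
    if denominator == "dinucleotide":
        observed = cpg_count / (length_bp - 1)
    elif denominator == "length":
        observed = cpg_count / length_bp
    else:
        raise ValueError("denominator must be 'dinucleotide' or 'length'")
    expected = (c_count / length_bp) * (g_count / length_bp)
    return observed / expected


def density_from_sequence(dna: str) -> tuple[int, int, int, int]:
    """Count CpG dinucleotides and C/G bases on the given strand.

    ``N`` bases are excluded from all counts but retained in the length
    (conservative toward undefined regions); any other character is an
    error.  CpG counting is on the given strand, but CG is its own
    reverse complement so the strand choice does not change the count.
    """
    seq = dna.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    c_count = seq.count("C")
    g_count = seq.count("G")
    cpg_count = seq.count("CG")  # non-overlapping == all occurrences for CG
    return cpg_count, c_count, g_count, len(seq)


def annotation_density(
    annotation: GenomicAnnotation, denominator: str = "dinucleotide"
) -> pd.DataFrame:
    """Per-promoter normalized CpG density from the annotation counts."""
    proms = annotation.promoters
    density = [
        normalized_cpg_density(
            r.cpg_count, r.c_count, r.g_count, r.length_bp, denominator
        )
        for r in proms.itertuples(index=False)
    ]
    return pd.DataFrame(
        {
            "promoter_id": proms["promoter_id"],
            "cpg_count": proms["cpg_count"],
            "c_count": proms["c_count"],
            "g_count": proms["g_count"],
            "length_bp": proms["length_bp"],
            "normalized_density": density,
        }
    )


def compare_density_groups(
    density: pd.DataFrame, promoter_results: pd.DataFrame
) -> pd.DataFrame:
    """Rank-sum contrasts of CpG density between promoter call groups.

    Three two-sided contrasts: promoters called up-in-CPA vs all other
    promoters, down-in-CPA vs all others, and up vs down.  Undefined
    densities are excluded, with the exclusion count reported.
    """
    from .promoter_stats import rank_sum

    merged = promoter_results[["promoter_id", "direction", "dm_call"]].merge(
        density[["promoter_id", "normalized_density"]], on="promoter_id", how="left"
    )
    defined = merged["normalized_density"].notna()
    n_undefined = int((~defined).sum())
    merged = merged[defined]
    d = merged["normalized_density"].to_numpy(dtype=float)
    up = (merged["dm_call"] & (merged["direction"] == CALL_UP)).to_numpy()
    down = (merged["dm_call"] & (merged["direction"] == CALL_DOWN)).to_numpy()

    contrasts = [
        ("up_vs_rest", d[up], d[~up]),
        ("down_vs_rest", d[down], d[~down]),
        ("up_vs_down", d[up], d[down]),
    ]
    rows = []
    for name, a, b in contrasts:
        if a.size < 2 or b.size < 2:
            raise ValueError(
                f"contrast {name!r} needs >= 2 promoters per group "
                f"(got {a.size} vs {b.size})"
            )
        rows.append(
            {
                "contrast": name,
                "n_a": a.size,
                "n_b": b.size,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "p_value": rank_sum(a, b, "two-sided"),
                "n_undefined_excluded": n_undefined,
            }
        )
    return pd.DataFrame(rows)
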