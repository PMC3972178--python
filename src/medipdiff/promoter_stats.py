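"""Promoter-level differential methylation calls by rank-sum aggregation.

A promoter is scored by asking whether its probes' moderated t-statistics
are enriched toward the top (hypermethylation in the case group) or the
bottom (hypomethylation) of all probe t-statistics on the array: a
Wilcoxon rank-sum test of the promoter's probes against every other
probe, one-sided in each direction.  The per-promoter p-value is the
smaller of the two one-sided p-values; Benjamini-Hochberg FDR is applied
once across the pooled list (a Bonferroni doubling of the minimum is
available via ``AnalysisConfig.direction_adjust``).  The final call
additionally requires at least one probe passing the probe-level rule in
the promoter's direction, tying statistical significance to a minimum
effect size.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GenomicAnnotation
from .config import AnalysisConfig
from .probe_stats import CALL_DOWN, CALL_UP

__all__ = [
    "rank_sum",
    "promoter_enrichment",
    "bh_fdr",
    "call_promoters",
    "promoter_pipeline",
]

#: Largest combined sample size for which the exact null distribution of
#: the rank-sum statistic is enumerated (ties force the approximation).
EXACT_LIMIT = 25


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size != values.size


def rank_sum(
    group_a, group_b, alternative: str = "two-sided"
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney U) p-value for two samples.

    ``alternative="greater"`` tests whether ``group_a`` tends to exceed
    ``group_b``.  The exact null distribution is used when the combined
    sample size is at most 25 and there are no ties; otherwise the
    normal approximation with midranks, tie correction and continuity
    correction is applied.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum requires both groups to be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"invalid alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    exact = pooled.size <= EXACT_LIMIT and not _has_ties(pooled)
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.pvalue)


def promoter_enrichment(
    probe_results: pd.DataFrame, annotation: GenomicAnnotation
) -> pd.DataFrame:
    """One-sided enrichment p-values of each promoter's probe t-statistics.

    For every promoter, its probes' ``moderated_t`` values are rank-sum
    tested against the t-statistics of all other probes on the array.
    Returns columns ``promoter_id, n_probes, p_up, p_down, direction,
    promoter_p``.  Promoters with no probes in ``probe_results`` are
    excluded with a warning; a single-promoter array has no background
    and is an error.
    """
    merged = probe_results.merge(
        annotation.probes[["probe_id", "promoter_id"]], on="probe_id", how="inner"
    )
    if merged.shape[0] != probe_results.shape[0]:
        raise ValueError("some probes in the results are missing from the annotation")
    present = merged["promoter_id"].unique()
    absent = set(annotation.promoters["promoter_id"]) - set(present)
    if absent:
        warnings.warn(
            f"{len(absent)} promoter(s) have no probes and are excluded",
            stacklevel=2,
        )
    if present.size < 2:
        raise ValueError(
            "promoter enrichment needs >= 2 promoters to form a background"
        )

    t_all = merged["moderated_t"].to_numpy(dtype=float)
    n_total = t_all.size
    groups = merged.groupby("promoter_id", sort=True)

    if n_total <= EXACT_LIMIT and not _has_ties(t_all):
        rows = []
        for pid, sub in groups:
            mask = merged["promoter_id"].to_numpy() == pid
            own, rest = t_all[mask], t_all[~mask]
            rows.append(
                (pid, own.size,
                 rank_sum(own, rest, "greater"),
                 rank_sum(own, rest, "less"))
            )
        result = pd.DataFrame(rows, columns=["promoter_id", "n_probes", "p_up", "p_down"])
    else:
        # Vectorized normal approximation: one global midrank pass, then a
        # per-promoter rank sum.  Matches scipy's asymptotic Mann-Whitney
        # with tie and continuity corrections (the combined sample is the
        # whole array for every promoter, so the tie term is shared).
        ranks = stats.rankdata(t_all)
        rank_sums = np.bincount(
            groups.ngroup().to_numpy(), weights=ranks, minlength=groups.ngroups
        )
        n1 = groups.size().to_numpy(dtype=float)
        n2 = n_total - n1
        u_up = rank_sums - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(t_all, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum())
        sigma = np.sqrt(
            n1 * n2 / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            p_up = stats.norm.sf((u_up - mu - 0.5) / sigma)
            p_down = stats.norm.sf((n1 * n2 - u_up - mu - 0.5) / sigma)
        result = pd.DataFrame(
            {
                "promoter_id": groups.size().index,
                "n_probes": n1.astype(int),
                "p_up": np.clip(p_up, 0.0, 1.0),
                "p_down": np.clip(p_down, 0.0, 1.0),
            }
        )
    result["direction"] = np.where(
        result["p_up"] <= result["p_down"], CALL_UP, CALL_DOWN
    )
    result["promoter_p"] = result[["p_up", "p_down"]].min(axis=1)
    return result.reset_index(drop=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_promoters(
    promoter_results: pd.DataFrame,
    probe_results: pd.DataFrame,
    annotation: GenomicAnnotation,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Apply FDR and the joint probe/promoter calling rule.

    Adds ``fdr`` (BH over the pooled promoter p-values), the count of
    probe-level calls agreeing with the promoter's direction, the main
    ``dm_call`` at ``promoter_fdr_threshold`` and the stricter
    ``strict_call`` at ``strict_fdr_threshold``.
    """
    config = config or AnalysisConfig()
    out = promoter_results.copy()
    p = out["promoter_p"].to_numpy(dtype=float)
    if config.direction_adjust == "bonferroni":
        p = np.minimum(2.0 * p, 1.0)
    out["fdr"] = bh_fdr(p)

    calls = probe_results.merge(
        annotation.probes[["probe_id", "promoter_id"]], on="probe_id", how="inner"
    )
    agree = calls.merge(
        out[["promoter_id", "direction"]], on="promoter_id", how="inner"
    )
    n_called = (
        agree[agree["probe_call"] == agree["direction"]]
        .groupby("promoter_id")
        .size()
    )
    out["n_called_probes"] = (
        out["promoter_id"].map(n_called).fillna(0).astype(int)
    )
    supported = out["n_called_probes"] >= 1
    out["dm_call"] = (out["fdr"] <= config.promoter_fdr_threshold) & supported
    out["strict_call"] = (out["fdr"] <= config.strict_fdr_threshold) & supported
    return out


def promoter_pipeline(
    probe_results: pd.DataFrame,
    annotation: GenomicAnnotation,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Enrichment, FDR and calls in one step from called probe results."""
    config = config or AnalysisConfig()
    enriched = promoter_enrichment(probe_results, annotation)
    return call_promoters(enriched, probe_results, annotation, config)
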