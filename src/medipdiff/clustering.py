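"""Spatial structure of differential methylation.

Three views, at increasing resolution:

* per-chromosome overrepresentation of differentially methylated
  promoters (one-sided Fisher exact / hypergeometric upper tail,
  BH-adjusted across chromosomes);
* a scan of fixed non-overlapping windows (500 kb by default, anchored
  at coordinate 0) testing each window, per direction, for an excess of
  differentially methylated probes relative to the rest of the genome;
* the distance decay of co-methylation: Pearson correlation of per-probe
  log2 fold differences over all intra-chromosomal probe pairs, binned
  by genomic separation, with a Fisher-z confidence interval and a
  permutation null envelope obtained by shuffling probe values within
  chromosomes (which preserves the marginal distribution and the pair
  geometry while destroying any positional dependence).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomicAnnotation
from .config import AnalysisConfig
from .probe_stats import CALL_DOWN, CALL_UP
from .promoter_stats import bh_fdr

__all__ = [
    "chromosome_enrichment",
    "window_scan",
    "enriched_windows",
    "fisher_z_ci",
    "distance_correlation",
]


def chromosome_enrichment(
    promoter_results: pd.DataFrame, annotation: GenomicAnnotation
) -> pd.DataFrame:
    """Per-chromosome overrepresentation of differential promoters.

    For each chromosome the 2x2 table [dm on chromosome, dm elsewhere;
    non-dm on chromosome, non-dm elsewhere] is tested one-sided for
    enrichment (hypergeometric upper tail); BH adjustment is applied
    across chromosomes.  ``neglog10_fdr`` gives the bar heights of the
    usual overrepresentation plot.
    """
    merged = promoter_results.merge(
        annotation.promoters[["promoter_id", "chrom"]], on="promoter_id", how="inner"
    )
    total = len(merged)
    total_dm = int(merged["dm_call"].sum())
    if total_dm == 0:
        raise ValueError("no differentially methylated promoters genome-wide")
    rows = []
    for chrom in annotation.chromosome_lengths:
        on_chrom = merged["chrom"] == chrom
        n_chrom = int(on_chrom.sum())
        if n_chrom == 0:
            warnings.warn(f"chromosome {chrom} has no promoters; skipped", stacklevel=2)
            continue
        k = int(merged.loc[on_chrom, "dm_call"].sum())
        # P(X >= k), X ~ Hypergeom(total, total_dm, n_chrom)
        p = float(stats.hypergeom.sf(k - 1, total, total_dm, n_chrom))
        rows.append(
            {
                "chrom": chrom,
                "n_promoters": n_chrom,
                "n_dm": k,
                "n_dm_elsewhere": total_dm - k,
                "n_promoters_elsewhere": total - n_chrom,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["neglog10_fdr"] = -np.log10(out["fdr"])
    return out


def _window_index(pos: np.ndarray, window_size: int) -> np.ndarray:
    return (pos // window_size).astype(int)


def window_scan(
    probe_results: pd.DataFrame,
    annotation: GenomicAnnotation,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Fixed-window scan for local excess of differential probes.

    Windows of ``config.window_size`` tile each chromosome from
    coordinate 0.  Per window and per direction a one-sided Fisher exact
    test (hypergeometric upper tail) compares the window's count of
    called probes with the genome-wide count; BH is applied across all
    windows separately per direction.  Probes are assigned to windows by
    interval midpoint.
    """
    config = config or AnalysisConfig()
    w = config.window_size
    merged = probe_results.merge(annotation.probes, on="probe_id", how="inner")
    mid = ((merged["start"] + merged["end"]) // 2).to_numpy()
    widx = _window_index(mid, w)

    rows = []
    total = len(merged)
    total_up = int((merged["probe_call"] == CALL_UP).sum())
    total_down = int((merged["probe_call"] == CALL_DOWN).sum())
    for chrom, length in annotation.chromosome_lengths.items():
        on_chrom = (merged["chrom"] == chrom).to_numpy()
        n_windows = int(np.ceil(length / w))
        counts_all = np.bincount(widx[on_chrom], minlength=n_windows)
        counts_up = np.bincount(
            widx[on_chrom & (merged["probe_call"] == CALL_UP).to_numpy()],
            minlength=n_windows,
        )
        counts_down = np.bincount(
            widx[on_chrom & (merged["probe_call"] == CALL_DOWN).to_numpy()],
            minlength=n_windows,
        )
        for i in range(n_windows):
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": i * w,
                    "window_end": min((i + 1) * w, length),
                    "n_probes": int(counts_all[i]),
                    "n_dm_probes_up": int(counts_up[i]),
                    "n_dm_probes_down": int(counts_down[i]),
                }
            )
    out = pd.DataFrame(rows)
    for direction, total_dm in (("up", total_up), ("down", total_down)):
        k = out[f"n_dm_probes_{direction}"].to_numpy()
        n = out["n_probes"].to_numpy()
        if total_dm == 0:
            p = np.ones(len(out))
        else:
            p = stats.hypergeom.sf(k - 1, total, total_dm, n)
        out[f"p_{direction}"] = np.minimum(p, 1.0)
        out[f"fdr_{direction}"] = bh_fdr(out[f"p_{direction}"].to_numpy())
    return out


def enriched_windows(
    windows: pd.DataFrame,
    promoter_results: pd.DataFrame,
    annotation: GenomicAnnotation,
    fdr_threshold: float = 0.2,
) -> pd.DataFrame:
    """Windows enriched in either direction, with their called promoters.

    Reproduces the shape of a per-region report: location (1-based
    inclusive in the output), direction, FDR and the gene symbols of
    differentially methylated promoters whose TSS falls in the window.
    """
    dm = promoter_results[promoter_results["dm_call"]].merge(
        annotation.promoters[["promoter_id", "gene_symbol", "chrom", "tss"]],
        on="promoter_id",
    )
    rows = []
    for _, win in windows.iterrows():
        for direction in ("up", "down"):
            if win[f"fdr_{direction}"] > fdr_threshold:
                continue
            in_win = dm[
                (dm["chrom"] == win["chrom"])
                & (dm["tss"] >= win["window_start"])
                & (dm["tss"] < win["window_end"])
                & (dm["direction"] == (CALL_UP if direction == "up" else CALL_DOWN))
            ]
            rows.append(
                {
                    "chrom": win["chrom"],
                    "start_1based": int(win["window_start"]) + 1,
                    "end_1based": int(win["window_end"]),
                    "direction": direction,
                    "fdr": win[f"fdr_{direction}"],
                    "n_dm_probes": win[f"n_dm_probes_{direction}"],
                    "genes": ",".join(sorted(in_win["gene_symbol"])),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_1based", "end_1based", "direction", "fdr",
                 "n_dm_probes", "genes"],
    ).sort_values("fdr").reset_index(drop=True)


def fisher_z_ci(r: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Fisher-z (arctanh) confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("Fisher-z interval needs n >= 4")
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + confidence / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def _pair_indices(
    positions: np.ndarray, max_distance: int
) -> tuple[np.ndarray, np.ndarray]:
    """All index pairs (i < j) with position separation <= max_distance.

    ``positions`` must be sorted ascending; uses searchsorted windows so
    memory scales with the number of qualifying pairs only.
    """
    left: list[np.ndarray] = []
    right: list[np.ndarray] = []
    hi = np.searchsorted(positions, positions + max_distance, side="right")
    for i in range(positions.size - 1):
        j_hi = hi[i]
        if j_hi > i + 1:
            right.append(np.arange(i + 1, j_hi))
            left.append(np.full(j_hi - i - 1, i))
    if not left:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(left), np.concatenate(right)


def _binned_pearson(
    x: np.ndarray, y: np.ndarray, bin_idx: np.ndarray, n_bins: int
) -> np.ndarray:
    """Pearson r per bin from streaming sums; nan for degenerate bins."""
    n = np.bincount(bin_idx, minlength=n_bins).astype(float)
    sx = np.bincount(bin_idx, weights=x, minlength=n_bins)
    sy = np.bincount(bin_idx, weights=y, minlength=n_bins)
    sxx = np.bincount(bin_idx, weights=x * x, minlength=n_bins)
    syy = np.bincount(bin_idx, weights=y * y, minlength=n_bins)
    sxy = np.bincount(bin_idx, weights=x * y, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        r = cov / np.sqrt(vx * vy)
        # Constant values leave only rounding noise in the variance terms.
        degenerate = (vx <= 1e-10 * np.abs(sxx)) | (vy <= 1e-10 * np.abs(syy))
    r[(n < 2) | degenerate | ~np.isfinite(r)] = np.nan
    return r


def distance_correlation(
    probe_results: pd.DataFrame,
    annotation: GenomicAnnotation,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Distance-binned correlation of probe log2 fold differences.

    For every intra-chromosomal probe pair separated by at most
    ``max_correlation_distance`` (midpoint distance), the pair of
    ``log2fc`` values enters the bin of its separation.  Reports the
    Pearson r per bin, its 95% Fisher-z interval, and a 95% null
    envelope from ``config.permutations`` within-chromosome value
    shuffles.  Bins with fewer than 10 pairs are reported with undefined
    r; bins where the values are constant are undefined as well.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.seed)
    bw = config.distance_bin_width
    n_bins = int(np.ceil(config.max_correlation_distance / bw))

    merged = probe_results.merge(annotation.probes, on="probe_id", how="inner")
    mid = ((merged["start"] + merged["end"]) / 2.0).to_numpy()

    # Pair structure per chromosome, built once and reused for the
    # permutation envelope (positions fixed, values shuffled).
    chrom_pairs = []
    for chrom in annotation.chromosome_lengths:
        on = (merged["chrom"] == chrom).to_numpy()
        if on.sum() < 2:
            continue
        pos = mid[on]
        vals = merged.loc[on, "log2fc"].to_numpy(dtype=float)
        order = np.argsort(pos, kind="stable")
        pos, vals = pos[order], vals[order]
        i_idx, j_idx = _pair_indices(pos, config.max_correlation_distance)
        if i_idx.size == 0:
            continue
        dist = pos[j_idx] - pos[i_idx]
        keep = dist < config.max_correlation_distance
        i_idx, j_idx, dist = i_idx[keep], j_idx[keep], dist[keep]
        bins = np.minimum((dist // bw).astype(int), n_bins - 1)
        chrom_pairs.append((vals, i_idx, j_idx, bins))

    if not chrom_pairs:
        raise ValueError("no chromosome has >= 2 probes within the distance cap")

    total_pairs = sum(p[1].size for p in chrom_pairs)
    if total_pairs > config.pair_cap * n_bins:
        # Uniform seeded thinning keeps memory and permutation cost bounded.
        frac = config.pair_cap * n_bins / total_pairs
        thinned = []
        for vals, i_idx, j_idx, bins in chrom_pairs:
            keep = rng.random(i_idx.size) < frac
            thinned.append((vals, i_idx[keep], j_idx[keep], bins[keep]))
        chrom_pairs = thinned

    def binned_r(value_arrays: list[np.ndarray]) -> np.ndarray:
        parts_x, parts_y, parts_b = [], [], []
        for (_, i_idx, j_idx, bins), vals in zip(chrom_pairs, value_arrays):
            parts_x.append(vals[i_idx])
            parts_y.append(vals[j_idx])
            parts_b.append(bins)
        return _binned_pearson(
            np.concatenate(parts_x), np.concatenate(parts_y),
            np.concatenate(parts_b), n_bins,
        )

    observed_values = [p[0] for p in chrom_pairs]
    r_obs = binned_r(observed_values)
    n_pairs = np.zeros(n_bins, dtype=int)
    for _, _, _, bins in chrom_pairs:
        n_pairs += np.bincount(bins, minlength=n_bins)
    r_obs[n_pairs < 10] = np.nan

    perm_r = np.full((config.permutations, n_bins), np.nan)
    for p in range(config.permutations):
        shuffled = [rng.permutation(v) for v in observed_values]
        perm_r[p] = binned_r(shuffled)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan bins
        null_lo = np.nanpercentile(perm_r, 2.5, axis=0)
        null_hi = np.nanpercentile(perm_r, 97.5, axis=0)

    ci_lo = np.full(n_bins, np.nan)
    ci_hi = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if np.isfinite(r_obs[b]) and abs(r_obs[b]) < 1 and n_pairs[b] >= 4:
            ci_lo[b], ci_hi[b] = fisher_z_ci(float(r_obs[b]), int(n_pairs[b]))
    return pd.DataFrame(
        {
            "bin_lower": np.arange(n_bins) * bw,
            "bin_upper": np.arange(1, n_bins + 1) * bw,
            "n_pairs": n_pairs,
            "pearson_r": r_obs,
            "ci_lower": ci_lo,
            "ci_upper": ci_hi,
            "null_lower": null_lo,
            "null_upper": null_hi,
        }
    )
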