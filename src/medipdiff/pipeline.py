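"""End-to-end orchestration: simulate or load, analyse, report.

A run executes probe statistics, promoter calls, the three spatial
analyses, the CpG-density contrasts and (optionally) the cohort report,
writing every stage table plus a manifest with config snapshots, file
digests and stage timings.  Identical inputs and seed reproduce
byte-identical outputs, which the manifest digests make checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import GenomicAnnotation, read_annotation
from .clustering import (
    chromosome_enrichment,
    distance_correlation,
    enriched_windows,
    window_scan,
)
from .cohort import cohort_report, load_reference_cohort
from .config import AnalysisConfig
from .cpg_density import annotation_density, compare_density_groups
from .matrix import MethylationMatrix, read_matrix
from .probe_stats import CALL_DOWN, CALL_UP, probe_pipeline
from .promoter_stats import promoter_pipeline
from .results_io import write_results
from .simulate import SyntheticConfig, generate_annotation, generate_matrix

__all__ = ["run_pipeline"]

logger = logging.getLogger("medipdiff")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    *,
    simulate: SyntheticConfig | None = None,
    matrix_path: str | Path | None = None,
    design_path: str | Path | None = None,
    probe_annotation_path: str | Path | None = None,
    promoter_annotation_path: str | Path | None = None,
    genome_path: str | Path | None = None,
    include_cohort: bool = True,
) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    Either pass ``simulate=SyntheticConfig(...)`` or all four input
    paths.  Outputs: probe_results.tsv, promoter_results.tsv,
    chromosome_enrichment.tsv, window_scan.tsv, enriched_windows.tsv,
    distance_correlation.tsv, density_contrasts.tsv, cohort_report.tsv,
    summary.json, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
        "inputs": {},
    }
    timings = manifest["stages"]

    def stage(name: str):
        start = time.perf_counter()

        def done() -> None:
            timings[name] = round(time.perf_counter() - start, 4)
            logger.info("stage %s finished in %.2fs", name, timings[name])

        return done

    done = stage("load")
    if simulate is not None:
        manifest["simulate"] = simulate.to_dict()
        annotation = generate_annotation(simulate)
        matrix, truth = generate_matrix(simulate, annotation)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.10g")
    else:
        needed = {
            "matrix_path": matrix_path,
            "design_path": design_path,
            "probe_annotation_path": probe_annotation_path,
            "promoter_annotation_path": promoter_annotation_path,
            "genome_path": genome_path,
        }
        missing = [k for k, v in needed.items() if v is None]
        if missing:
            raise ValueError(f"missing inputs (and no simulation requested): {missing}")
        for key, value in needed.items():
            manifest["inputs"][key] = {"path": str(value), "sha256": _digest(Path(value))}
        annotation = read_annotation(
            probe_annotation_path, promoter_annotation_path, genome_path
        )
        matrix = read_matrix(matrix_path, design_path)
    done()

    done = stage("probe_stats")
    probe_results, prior = probe_pipeline(matrix, config)
    write_results(probe_results, out / "probe_results.tsv")
    n_up = int((probe_results["probe_call"] == CALL_UP).sum())
    n_down = int((probe_results["probe_call"] == CALL_DOWN).sum())
    logger.info("probes tested=%d called up=%d down=%d", len(probe_results), n_up, n_down)
    done()

    done = stage("promoter_stats")
    promoter_results = promoter_pipeline(probe_results, annotation, config)
    write_results(promoter_results, out / "promoter_results.tsv")
    dm = promoter_results[promoter_results["dm_call"]]
    logger.info(
        "promoters called=%d (up=%d down=%d) strict=%d",
        len(dm),
        int((dm["direction"] == CALL_UP).sum()),
        int((dm["direction"] == CALL_DOWN).sum()),
        int(promoter_results["strict_call"].sum()),
    )
    done()

    done = stage("genomic_clustering")
    if len(dm) > 0:
        chrom_enrich = chromosome_enrichment(promoter_results, annotation)
    else:
        chrom_enrich = pd.DataFrame()
    write_results(chrom_enrich, out / "chromosome_enrichment.tsv")
    windows = window_scan(probe_results, annotation, config)
    write_results(windows, out / "window_scan.tsv")
    enriched = enriched_windows(
        windows, promoter_results, annotation, config.promoter_fdr_threshold
    )
    write_results(enriched, out / "enriched_windows.tsv")
    dist_corr = distance_correlation(probe_results, annotation, config)
    write_results(dist_corr, out / "distance_correlation.tsv")
    logger.info("windows enriched=%d", len(enriched))
    done()

    done = stage("cpg_density")
    density = annotation_density(annotation, config.density_denominator)
    write_results(density, out / "cpg_density.tsv")
    try:
        contrasts = compare_density_groups(density, promoter_results)
    except ValueError as exc:
        logger.warning("density contrasts skipped: %s", exc)
        contrasts = pd.DataFrame()
    write_results(contrasts, out / "density_contrasts.tsv")
    done()

    if include_cohort:
        done = stage("cohort_stats")
        report = cohort_report(load_reference_cohort())
        write_results(report, out / "cohort_report.tsv")
        done()

    summary = {
        "n_probes": len(probe_results),
        "n_probes_called_up": n_up,
        "n_probes_called_down": n_down,
        "n_promoters": len(promoter_results),
        "n_dm_promoters": len(dm),
        "n_dm_up": int((dm["direction"] == CALL_UP).sum()),
        "n_dm_down": int((dm["direction"] == CALL_DOWN).sum()),
        "n_strict_promoters": int(promoter_results["strict_call"].sum()),
        "n_enriched_windows": len(enriched),
        "prior_df": prior.prior_df if prior.prior_df != float("inf") else "inf",
        "prior_variance": prior.prior_variance,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    for f in sorted(out.glob("*.tsv")) + [out / "summary.json"]:
        manifest["outputs"][f.name] = _digest(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
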