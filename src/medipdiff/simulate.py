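"""Synthetic promoter-tiling-array data with planted group differences.

The generator emulates the statistical structure the analysis assumes:
~20 000 promoters tiled by a variable number of probes over the
-1000..+250 bp region around each TSS, two groups of unequal size
(8 cases vs 12 controls), i.i.d. Gaussian probe noise on the log2
MeDIP/input scale, and a planted fraction of differentially methylated
promoters whose probes all receive a signed log2 shift in the case group
only.  Optional features give the spatial analyses a controllable ground
truth: planted promoters can be confined to random megabase-scale
genomic blocks (one shared direction per block), and the planted
direction can be linked to promoter CpG density (hypermethylated
promoters drawn CpG-rich, hypomethylated CpG-poor), mirroring the
density contrast seen on real arrays.

Probe values are generated directly as log2 ratios; no
immunoprecipitation-enrichment chemistry is modelled, because the
analysis consumes log ratios and that is the right abstraction level.
All randomness flows from a single seed through per-stage child streams,
so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    DOWNSTREAM_BP,
    UPSTREAM_BP,
    GenomicAnnotation,
    write_annotation,
)
from .cohort import CohortTable, CountVariable, SummaryVariable
from .cpg_density import normalized_cpg_density
from .matrix import GROUP_CASE, GROUP_CONTROL, MethylationMatrix, write_matrix
from .probe_stats import CALL_DOWN, CALL_NONE, CALL_UP

__all__ = [
    "SyntheticConfig",
    "generate_annotation",
    "generate_matrix",
    "generate_cohort",
    "simulate_dataset",
]

REGION_SPAN = UPSTREAM_BP + DOWNSTREAM_BP  # 1250 bp tiled per promoter
PROBE_LENGTH = 50


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs.

    Defaults mirror the study design this package models: ~20 000
    promoters on autosome-scale chromosomes, ~12 probes per promoter
    (244 K probes / 20 K promoters), 8 cases vs 12 controls, and a 5%
    planted fraction of differential promoters with a 0.5 log2 shift —
    the middle of the per-probe fold-difference range the original
    validation experiments targeted.  ``noise_sd`` = 0.25 gives per-probe
    group-difference noise of ~0.11 log2 units, large enough that single
    probes are unreliable and promoter aggregation is needed.
    """

    n_chromosomes: int = 22
    chromosome_length: int = 140_000_000
    n_promoters: int = 20_000
    probes_per_promoter: tuple[int, int] = (8, 16)
    n_cpa: int = 8
    n_control: int = 12
    planted_fraction: float = 0.05
    effect_log2: float = 0.5
    effect_sd: float = 0.15
    noise_sd: float = 0.25
    cluster_block_length: int = 0
    cpg_density_link: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.n_cpa < 2 or self.n_control < 2:
            raise ValueError("both groups need n >= 2")
        for name in ("n_chromosomes", "chromosome_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_promoters < 0:
            raise ValueError("n_promoters must be >= 0")
        lo, hi = self.probes_per_promoter
        if not (1 <= lo <= hi):
            raise ValueError("probes_per_promoter must satisfy 1 <= min <= max")
        if self.noise_sd <= 0 or self.effect_sd < 0:
            raise ValueError("noise_sd must be > 0 and effect_sd >= 0")
        if self.cluster_block_length < 0:
            raise ValueError("cluster_block_length must be >= 0")
        if self.cpg_density_link not in ("none", "directional"):
            raise ValueError("cpg_density_link must be 'none' or 'directional'")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage child stream of the config seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[stage])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["probes_per_promoter"] = list(d["probes_per_promoter"])
        return d


def _place_regions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Uniformly place n non-overlapping REGION_SPAN intervals on [0, length)."""
    slack = length - n * REGION_SPAN
    if slack < 0:
        raise ValueError(
            f"cannot place {n} promoter regions of {REGION_SPAN} bp on a "
            f"{length} bp chromosome; use longer chromosomes or fewer promoters"
        )
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    return gaps + np.arange(n) * REGION_SPAN


def generate_annotation(config: SyntheticConfig) -> GenomicAnnotation:
    """Random promoter and probe annotation for a synthetic genome.

    Promoters are placed uniformly at random without overlap, each tiled
    by a configured number of probes inside its -1000..+250 region.
    CpG/C/G counts are drawn from a two-component (CpG-island-like vs
    depleted) mixture so normalized CpG density spans a realistic
    bimodal range.
    """
    rng = config.rng(0)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    lengths = {c: config.chromosome_length for c in chroms}
    if config.n_promoters == 0:
        empty_probes = pd.DataFrame(
            columns=["probe_id", "chrom", "start", "end", "promoter_id"]
        )
        empty_proms = pd.DataFrame(
            columns=["promoter_id", "gene_symbol", "chrom", "tss", "strand",
                     "region_start", "region_end", "cpg_count", "c_count",
                     "g_count", "length_bp"]
        )
        return GenomicAnnotation(lengths, empty_probes, empty_proms)

    per_chrom = rng.multinomial(
        config.n_promoters, np.full(config.n_chromosomes, 1.0 / config.n_chromosomes)
    )
    prom_rows: list[tuple] = []
    probe_rows: list[tuple] = []
    prom_idx = 0
    probe_idx = 0
    lo, hi = config.probes_per_promoter
    for chrom, n_on_chrom in zip(chroms, per_chrom):
        if n_on_chrom == 0:
            continue
        starts = _place_regions(rng, int(n_on_chrom), config.chromosome_length)
        strands = rng.choice(["+", "-"], size=n_on_chrom)
        island = rng.random(n_on_chrom) < 0.5
        gc = np.where(
            island,
            rng.normal(0.60, 0.04, n_on_chrom),
            rng.normal(0.40, 0.03, n_on_chrom),
        ).clip(0.25, 0.75)
        target_density = np.where(
            island,
            rng.normal(0.75, 0.10, n_on_chrom),
            rng.normal(0.20, 0.05, n_on_chrom),
        ).clip(0.02, 1.2)
        n_probes = rng.integers(lo, hi + 1, size=n_on_chrom)
        for i in range(n_on_chrom):
            region_start = int(starts[i])
            region_end = region_start + REGION_SPAN
            strand = str(strands[i])
            tss = region_start + (UPSTREAM_BP if strand == "+" else DOWNSTREAM_BP)
            length = REGION_SPAN
            c_count = int(rng.binomial(length, gc[i] / 2))
            g_count = int(rng.binomial(length, gc[i] / 2))
            expected = (c_count / length) * (g_count / length) * (length - 1)
            cpg_count = int(np.clip(round(target_density[i] * expected), 0,
                                    min(c_count, g_count)))
            pid = f"prom{prom_idx:06d}"
            prom_rows.append(
                (pid, f"GENE{prom_idx:06d}", chrom, tss, strand, region_start,
                 region_end, cpg_count, c_count, g_count, length)
            )
            k = int(n_probes[i])
            offsets = np.round(np.linspace(0, REGION_SPAN - PROBE_LENGTH, k)).astype(int)
            for off in offsets:
                probe_rows.append(
                    (f"p{probe_idx:07d}", chrom, region_start + int(off),
                     region_start + int(off) + PROBE_LENGTH, pid)
                )
                probe_idx += 1
            prom_idx += 1
    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "start", "end", "promoter_id"]
    )
    promoters = pd.DataFrame(
        prom_rows,
        columns=["promoter_id", "gene_symbol", "chrom", "tss", "strand",
                 "region_start", "region_end", "cpg_count", "c_count",
                 "g_count", "length_bp"],
    )
    return GenomicAnnotation(lengths, probes, promoters)


def _choose_planted(
    config: SyntheticConfig,
    annotation: GenomicAnnotation,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices (into the promoter table) of planted promoters."""
    n_target = int(round(config.planted_fraction * annotation.n_promoters))
    if n_target == 0:
        return np.empty(0, dtype=int)
    if config.cluster_block_length == 0:
        return rng.choice(annotation.n_promoters, size=n_target, replace=False)
    proms = annotation.promoters
    chroms = list(annotation.chromosome_lengths)
    chosen: list[int] = []
    seen: set[int] = set()
    guard = 0
    while len(chosen) < n_target:
        guard += 1
        if guard > 10_000:
            raise ValueError(
                "cannot fill the planted fraction from clustered blocks; "
                "increase cluster_block_length or promoter density"
            )
        chrom = chroms[rng.integers(len(chroms))]
        length = annotation.chromosome_lengths[chrom]
        start = int(rng.integers(0, max(length - config.cluster_block_length, 1)))
        in_block = proms.index[
            (proms["chrom"] == chrom)
            & (proms["tss"] >= start)
            & (proms["tss"] < start + config.cluster_block_length)
        ]
        fresh = [i for i in in_block if i not in seen]
        seen.update(fresh)
        chosen.extend(fresh)
    return np.array(chosen[:n_target], dtype=int)


def generate_matrix(
    config: SyntheticConfig, annotation: GenomicAnnotation
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Probe log2-ratio matrix plus the planted-promoter truth table.

    Unplanted probes are Normal(0, noise_sd) in both groups; every probe
    of a planted promoter receives the promoter's signed shift in the
    case samples only.  The truth table has one row per promoter with
    ``planted``, ``direction`` and the drawn ``effect``.
    """
    rng = config.rng(1)
    n_samples = config.n_cpa + config.n_control
    sample_ids = [f"CPA_{i + 1:02d}" for i in range(config.n_cpa)] + [
        f"CTRL_{i + 1:02d}" for i in range(config.n_control)
    ]
    labels = [GROUP_CASE] * config.n_cpa + [GROUP_CONTROL] * config.n_control
    values = rng.normal(0.0, config.noise_sd, size=(annotation.n_probes, n_samples))

    proms = annotation.promoters
    planted_idx = _choose_planted(config, annotation, rng)
    effects = np.zeros(annotation.n_promoters)
    if planted_idx.size:
        if config.cpg_density_link == "directional":
            density = np.array(
                [
                    normalized_cpg_density(r.cpg_count, r.c_count, r.g_count, r.length_bp)
                    for r in proms.itertuples(index=False)
                ]
            )
            median = np.nanmedian(density)
            p_up = np.where(density[planted_idx] > median, 0.9, 0.1)
            signs = np.where(rng.random(planted_idx.size) < p_up, 1.0, -1.0)
        elif config.cluster_block_length > 0:
            # One shared direction per clustered neighbourhood: promoters
            # within cluster_block_length of the previous planted promoter
            # on the same chromosome inherit its sign.
            order = np.argsort(planted_idx)
            signs = np.empty(planted_idx.size)
            prev_chrom, prev_tss, prev_sign = None, None, 1.0
            for pos in order:
                row = proms.iloc[planted_idx[pos]]
                if (
                    row["chrom"] == prev_chrom
                    and prev_tss is not None
                    and abs(int(row["tss"]) - prev_tss) <= config.cluster_block_length
                ):
                    signs[pos] = prev_sign
                else:
                    prev_sign = 1.0 if rng.random() < 0.5 else -1.0
                    signs[pos] = prev_sign
                prev_chrom, prev_tss = row["chrom"], int(row["tss"])
        else:
            signs = rng.choice([-1.0, 1.0], size=planted_idx.size)
        magnitudes = rng.normal(config.effect_log2, config.effect_sd, planted_idx.size)
        effects[planted_idx] = signs * magnitudes

    if planted_idx.size:
        effect_by_pid = dict(zip(proms["promoter_id"], effects))
        probe_effects = annotation.probes["promoter_id"].map(effect_by_pid).to_numpy()
        case_cols = np.array([g == GROUP_CASE for g in labels])
        values[:, case_cols] += probe_effects[:, None]

    truth = pd.DataFrame(
        {
            "promoter_id": proms["promoter_id"],
            "planted": effects != 0.0,
            "direction": np.where(
                effects > 0, CALL_UP, np.where(effects < 0, CALL_DOWN, CALL_NONE)
            ),
            "effect": effects,
        }
    )
    matrix = MethylationMatrix(
        values, annotation.probes["probe_id"].tolist(), sample_ids, labels
    )
    return matrix, truth


def generate_cohort(
    config: SyntheticConfig,
    n_summary: int = 3,
    n_count: int = 3,
) -> CohortTable:
    """A random cohort-characteristics fixture matching the two-group design.

    Continuous variables get group means drawn near each other (null-ish
    differences), binary variables get binomial counts; sizes are the
    config's group sizes.  Useful for exercising the cohort report on
    inputs with a known shape.
    """
    rng = config.rng(2)
    variables: list[SummaryVariable | CountVariable] = []
    for i in range(n_summary):
        base = rng.uniform(0, 10)
        sd = rng.uniform(0.5, 3.0)
        variables.append(
            SummaryVariable(
                f"score_{i + 1}",
                round(base + rng.normal(0, sd / 3), 2), round(sd, 2), config.n_control,
                round(base + rng.normal(0, sd / 3), 2), round(sd * rng.uniform(0.8, 1.2), 2),
                config.n_cpa,
            )
        )
    for i in range(n_count):
        p = rng.uniform(0.1, 0.7)
        a_yes = int(rng.binomial(config.n_control, p))
        b_yes = int(rng.binomial(config.n_cpa, p))
        variables.append(
            CountVariable(
                f"record_{i + 1}",
                a_yes, config.n_control - a_yes, b_yes, config.n_cpa - b_yes,
            )
        )
    return CohortTable(variables)


def simulate_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a full dataset (annotation, matrix, design, truth).

    Returns the mapping of artifact names to file paths; a JSON snapshot
    of the config is included so the run is reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = generate_annotation(config)
    matrix, truth = generate_matrix(config, annotation)
    paths = {
        "probes": out / "probes.tsv",
        "promoters": out / "promoters.tsv",
        "genome": out / "genome.tsv",
        "matrix": out / "matrix.tsv",
        "design": out / "design.tsv",
        "truth": out / "truth.tsv",
        "config": out / "synthetic_config.json",
    }
    write_annotation(annotation, paths["probes"], paths["promoters"], paths["genome"])
    write_matrix(matrix, paths["matrix"], paths["design"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    return paths
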