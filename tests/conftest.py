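import numpy as np
import pandas as pd
import pytest

from medipdiff import (
    AnalysisConfig,
    GenomicAnnotation,
    MethylationMatrix,
    SyntheticConfig,
)


def make_annotation(
    promoter_specs: list[tuple[str, str, int, str]],
    probes_per_promoter: int = 3,
    chrom_length: int = 1_000_000,
) -> GenomicAnnotation:
    """Tiny annotation builder: promoter_specs = (pid, chrom, tss, strand)."""
    prom_rows, probe_rows = [], []
    k = 0
    for pid, chrom, tss, strand in promoter_specs:
        if strand == "+":
            start, end = tss - 1000, tss + 250
        else:
            start, end = tss - 250, tss + 1000
        prom_rows.append(
            (pid, f"GENE_{pid}", chrom, tss, strand, start, end, 60, 300, 300, 1250)
        )
        for j in range(probes_per_promoter):
            probe_rows.append(
                (f"{pid}_probe{j}", chrom, start + j * 60, start + j * 60 + 50, pid)
            )
            k += 1
    chroms = {chrom for _, chrom, _, _ in promoter_specs}
    return GenomicAnnotation(
        {c: chrom_length for c in chroms},
        pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "start", "end", "promoter_id"]),
        pd.DataFrame(
            prom_rows,
            columns=["promoter_id", "gene_symbol", "chrom", "tss", "strand",
                     "region_start", "region_end", "cpg_count", "c_count",
                     "g_count", "length_bp"],
        ),
    )


def make_matrix(values, n_case: int = 2, n_control: int = 2,
                probe_ids=None) -> MethylationMatrix:
    values = np.asarray(values, dtype=float)
    if probe_ids is None:
        probe_ids = [f"p{i}" for i in range(values.shape[0])]
    n = n_case + n_control
    assert values.shape[1] == n
    return MethylationMatrix(
        values,
        probe_ids,
        [f"s{i}" for i in range(n)],
        ["CPA"] * n_case + ["control"] * n_control,
    )


@pytest.fixture
def default_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def small_sim() -> SyntheticConfig:
    """A desk-scale study: 300 promoters, 3 chromosomes, 8 vs 12 samples."""
    return SyntheticConfig(
        n_chromosomes=3,
        chromosome_length=5_000_000,
        n_promoters=300,
        probes_per_promoter=(3, 6),
        seed=11,
    )


@pytest.fixture
def small_dataset(small_sim):
    from medipdiff import generate_annotation, generate_matrix

    annotation = generate_annotation(small_sim)
    matrix, truth = generate_matrix(small_sim, annotation)
    return annotation, matrix, truth
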