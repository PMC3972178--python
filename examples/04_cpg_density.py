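"""Normalized CpG density and its contrast between call groups.

Normalized CpG density = observed CpG dinucleotide density divided by
the density expected from the C and G base composition; CpG-island-like
promoters sit near 1, bulk DNA far below.  With a directional link
planted between density and methylation direction, the up-vs-down
contrast becomes strongly significant.
"""

from medipdiff import (
    SyntheticConfig,
    annotation_density,
    compare_density_groups,
    density_from_sequence,
    generate_annotation,
    generate_matrix,
    normalized_cpg_density,
    probe_pipeline,
    promoter_pipeline,
)

print("hand-checkable values:")
for seq in ("CGCGCG", "ACGT"):
    counts = density_from_sequence(seq)
    print(f"  {seq}: cpg={counts[0]} c={counts[1]} g={counts[2]} ->"
          f" density {normalized_cpg_density(*counts):.4f}")

config = SyntheticConfig(
    n_chromosomes=3,
    chromosome_length=10_000_000,
    n_promoters=600,
    probes_per_promoter=(3, 6),
    planted_fraction=0.08,
    effect_log2=1.0,
    cpg_density_link="directional",
    seed=4,
)
annotation = generate_annotation(config)
matrix, _ = generate_matrix(config, annotation)
probe_results, _ = probe_pipeline(matrix)
promoter_results = promoter_pipeline(probe_results, annotation)
contrasts = compare_density_groups(annotation_density(annotation), promoter_results)
print(contrasts.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
# up_vs_down compares CpG density between promoters hyper- vs
# hypomethylated in the case group (two-sided rank-sum); the planted
# directional link drives its p-value far below 0.01.
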