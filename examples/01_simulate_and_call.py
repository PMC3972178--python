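"""Simulate a two-group promoter methylation study and call differential promoters.

Generates a small synthetic MeDIP tiling-array dataset (8 cases vs 12
controls, 5% of promoters planted with a 1.0 log2 shift), runs the
probe-level moderated-t and promoter-level rank-sum stages, and scores
the calls against the planted truth.
"""

from medipdiff import (
    SyntheticConfig,
    generate_annotation,
    generate_matrix,
    probe_pipeline,
    promoter_pipeline,
)

config = SyntheticConfig(
    n_chromosomes=3,
    chromosome_length=10_000_000,
    n_promoters=1000,
    probes_per_promoter=(3, 6),
    planted_fraction=0.05,
    effect_log2=1.0,
    noise_sd=0.25,
    seed=1,
)
annotation = generate_annotation(config)
matrix, truth = generate_matrix(config, annotation)
print(f"simulated {annotation.n_probes} probes in {annotation.n_promoters} promoters,"
      f" {truth['planted'].sum()} planted")

probe_results, prior = probe_pipeline(matrix)
print(f"empirical-Bayes prior: d0 = {prior.prior_df:.2f}, s0^2 = {prior.prior_variance:.4f}")
print(f"probes called: {(probe_results['probe_call'] != 'none').sum()}")

promoter_results = promoter_pipeline(probe_results, annotation)
scored = promoter_results.merge(truth, on="promoter_id")
called = scored[scored["dm_call"]]
tp = called["planted"].sum()
print(f"promoters called differentially methylated: {len(called)} "
      f"({(called['direction_x'] == 'up_in_cpa').sum()} up, "
      f"{(called['direction_x'] == 'down_in_cpa').sum()} down)")
print(f"sensitivity = {tp / truth['planted'].sum():.2f}, "
      f"false-discovery proportion = {(len(called) - tp) / max(len(called), 1):.2f}")
# Sensitivity near 1 and FDP well under the 0.2 FDR target show the
# promoter aggregation recovering the planted signal at this effect size.
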