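"""Distance decay of co-methylation with a permutation null envelope.

Probe-level log2 fold differences are correlated over all
intra-chromosomal probe pairs, binned by genomic separation.  Planted
megabase-scale blocks produce correlation that is clearly above the
null envelope at sub-megabase distances and indistinguishable from it
several megabases out.
"""

import numpy as np
import pandas as pd

from medipdiff import AnalysisConfig, GenomicAnnotation, distance_correlation

rng = np.random.default_rng(5)
spacing, chrom_len, n_chrom = 400_000, 50_000_000, 10
n = chrom_len // spacing
prom_rows, probe_rows, values = [], [], []
k = 0
for c in range(n_chrom):
    chrom = f"chr{c + 1}"
    block_effect = rng.normal(0, 0.15, chrom_len // 1_000_000 + 1)  # 1 Mb blocks
    pos = 2000 + spacing * np.arange(n)
    for p in pos:
        pid = f"prom{k:05d}"
        prom_rows.append((pid, f"GENE{k:05d}", chrom, int(p), "+", int(p) - 1000,
                          int(p) + 250, 60, 300, 300, 1250))
        probe_rows.append((f"pr{k:05d}", chrom, int(p) - 500, int(p) - 450, pid))
        k += 1
    values.append(block_effect[pos // 1_000_000] + rng.normal(0, 0.114, n))

annotation = GenomicAnnotation(
    {f"chr{c + 1}": chrom_len for c in range(n_chrom)},
    pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "start", "end", "promoter_id"]),
    pd.DataFrame(prom_rows, columns=["promoter_id", "gene_symbol", "chrom", "tss",
                                     "strand", "region_start", "region_end",
                                     "cpg_count", "c_count", "g_count", "length_bp"]),
)
frame = pd.DataFrame({
    "probe_id": [r[0] for r in probe_rows],
    "log2fc": np.concatenate(values),
    "probe_call": "none",
})
config = AnalysisConfig(max_correlation_distance=6_000_000,
                        distance_bin_width=500_000, permutations=200, seed=5)
out = distance_correlation(frame, annotation, config)
cols = ["bin_lower", "bin_upper", "n_pairs", "pearson_r", "ci_lower", "ci_upper",
        "null_lower", "null_upper"]
print(out[cols].to_string(index=False, float_format=lambda x: f"{x:.4f}"))
# pearson_r decays from ~0.3-0.5 in the first bin toward zero beyond the
# 1 Mb block size; where the Fisher-z CI clears null_upper the
# correlation is beyond what shuffled probe positions can produce.
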