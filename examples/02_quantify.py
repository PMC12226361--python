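"""From precursor report to analysis-ready protein matrix.

Stages: drop single-peptide proteins -> scale every sample's total
intensity to 1e7 -> aggregate precursors per protein -> impute missing
cells at the per-sample 1% quantile -> log2.
"""
import numpy as np

import plmatch as pm

table, design, _, _ = pm.simulate_experiment(pm.SimConfig(seed=1))

filtered = pm.filter_min_unique_peptides(table, k=2)
print(f"unique-peptide filter (k=2): {len(table.proteins)} -> "
      f"{len(filtered.proteins)} proteins")

normalized = pm.normalize_total_intensity(filtered)
print("per-sample totals after normalization:",
      np.unique(np.round(normalized.sample_totals().to_numpy())))

for method in ("sum", "top1", "maxlfq"):
    matrix = pm.aggregate(normalized, method)
    missing = float(matrix.values.isna().mean().mean())
    print(f"  {method:>6s}: {matrix.values.shape[0]} proteins x "
          f"{matrix.values.shape[1]} samples, {missing:.1%} cells missing")

matrix = pm.aggregate(normalized, "sum")
matrix = pm.impute_quantile(matrix, q=0.01)
matrix = pm.log2_transform(matrix)
print("final matrix flags: normalized=%s imputed=%s log2=%s"
      % (matrix.normalized, matrix.imputed, matrix.log2))
print("log2 intensity range: %.1f .. %.1f"
      % (matrix.values.min().min(), matrix.values.max().max()))
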