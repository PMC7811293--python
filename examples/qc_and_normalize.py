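"""Per-cell quality control and median-depth normalization.

Flags cells whose count depth or detected-gene count falls below 50% of
the cohort median (plus a mitochondrial-fraction cutoff when mito genes
are supplied), then rescales surviving cells to the median depth and
log-transforms.
"""

import numpy as np
import pandas as pd

from cellsort import ExpressionMatrix, compute_qc_metrics, normalize, qc_filter

rng = np.random.default_rng(1)
n_genes, n_cells = 200, 300
depth_scale = rng.lognormal(0.0, 0.6, size=n_cells)  # uneven library sizes
counts = rng.poisson(depth_scale * rng.lognormal(0, 1, size=(n_genes, 1)))
matrix = ExpressionMatrix(pd.DataFrame(
    counts.astype(float),
    index=[f"g{i}" for i in range(n_genes - 5)] + [f"MT-{i}" for i in range(5)],
    columns=[f"cell{j}" for j in range(n_cells)],
)).drop_empty()

metrics = compute_qc_metrics(matrix, [f"MT-{i}" for i in range(5)])
result = qc_filter(metrics)

print("QC thresholds:", {k: None if v is None else round(v, 3)
                         for k, v in result.thresholds.items()})
print(f"cells passing QC: {int(result.passed.sum())}/{matrix.n_cells}")
print("failures by rule:", result.reasons.sum().to_dict())

kept = matrix.subset_cells(result.passed.index[result.passed]).drop_empty()
lognorm = normalize(kept)
totals = np.expm1(lognorm.values).sum(axis=0)
# after normalization every cell's pre-log total equals the median depth
print(f"pre-log totals after scaling: {totals.min():.6f}..{totals.max():.6f}")
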