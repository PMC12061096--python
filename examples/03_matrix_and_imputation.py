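"""Intensity matrix assembly, normalization, filtering, imputation.

Shows the quantification path: long-format intensities -> log2 matrix
with a missingness mask -> median normalization -> 70%-valid filter ->
left-censored imputation (shift 1.8 SD, width 0.3 SD).
"""

import numpy as np

import glycopipe as gp

cfg = gp.SimulationConfig(n_features=800)
meta = gp.simulate_cohort(cfg, seed=5)
matrix, truth = gp.simulate_intensity_matrix(meta, cfg, seed=5)

rep = gp.missingness_report(matrix)
print(f"features: {matrix.n_features}, samples: {len(matrix.samples)}")
print(f"missing cells: {100 * rep['overall']:.1f}% (left-censored, intensity-dependent)")

norm = gp.normalize_matrix(matrix)
meds = norm.values.where(norm.observed).median(axis=0)
print(f"after normalization, sample medians span {meds.min():.3f}..{meds.max():.3f}")

imputed = gp.impute_missing(norm, shift=1.8, width=0.3, seed=5)
obs = norm.observed.to_numpy()
cells = imputed.values.to_numpy()
print(f"imputed-cell mean {cells[~obs].mean():.2f} vs observed mean {cells[obs].mean():.2f}"
      " (imputed values sit below the detection limit, as intended)")

kept = gp.filter_valid_values(imputed, meta, min_frac=0.70, validity_strata="group_time")
print(f"70%-valid filter: {matrix.n_features} -> {kept.n_features} features"
      " (counted on the original mask, never on imputed values)")
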