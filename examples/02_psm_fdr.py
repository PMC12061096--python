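"""Combined P-score FDR control on a simulated PSM table.

Fits the logistic P-score on Log-P and Delta-Mod, picks the lowest
threshold with decoy-FDR < 1%, applies the hard Score > 200 cut, and
reports the effective FDR of the survivors.
"""

import glycopipe as gp
from glycopipe.psm import choose_pscore_threshold

cfg = gp.SimulationConfig()  # 5,000 targets (5% incorrect), 500 decoys
psms, truth = gp.simulate_psm_table(cfg, seed=3)
print(f"simulated PSMs: {len(psms)} ({int(psms['is_decoy'].sum())} decoys)")

model, scored = gp.fit_pscore(psms)
print(f"P-score model: logit = {model.intercept:+.3f} "
      f"{model.coef_log_p:+.3f}*LogP {model.coef_delta_mod:+.3f}*DeltaMod")

threshold, passed = choose_pscore_threshold(scored, fdr_target=0.01)
survivors = gp.apply_hard_filters(passed, score_min=200.0)
eff = gp.estimate_effective_fdr(survivors)
print(f"P-score threshold: {threshold:.4f} -> {len(passed)} PSMs pass")
print(f"after Score > 200: {len(survivors)} PSMs, effective FDR {100 * eff:.2f}%")

# ground truth the pipeline never sees: realized false-match proportion
surv_targets = passed[~passed["is_decoy"]]
fmp = 1.0 - truth[surv_targets.index].mean()
print(f"true false-match proportion among surviving targets: {100 * fmp:.2f}%")
# The decoy estimate should bound the truth: decoys and incorrect
# targets share a score distribution, so #decoys tracks #false targets.
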