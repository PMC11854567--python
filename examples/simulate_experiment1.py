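"""Run a small Monte-Carlo replication study of the linear MAR design.

Reproduces the selection-performance summary (TP / FP / UF / CF / OF, bias /
SD / RMSE) at a reduced scale: 40 replications of the (n, p+1, q+1) =
(200, 17, 9) configuration under the correctly specified logistic mechanism.
"""

import numpy as np

from petlik import ExperimentConfig, run_replications

cfg = ExperimentConfig(experiment="exp1_linear", n=200, p=16, q=8,
                       mechanism="M1", reps=40, seed=3, grid_num=8)
summary = run_replications(cfg)

b = summary.beta_selection
print(f"outcome block: TP = {b['tp']:.2f} of {b['n_zero']} true zeros, "
      f"FP = {b['fp']:.2f}, UF/CF/OF = {b['uf']:.2f}/{b['cf']:.2f}/{b['of']:.2f}")
g = summary.gamma_selection
print(f"propensity block: TP = {g['tp']:.2f} of {g['n_zero']}, CF = {g['cf']:.2f}")
acc = summary.beta_accuracy
print("bias of active coefficients:", np.round(acc["bias"][:3], 3))
print("RMSE of active coefficients:", np.round(acc["rmse"][:3], 3))

# TP near its maximum and CF well above one half indicate that the BIC-tuned
# SCAD penalty recovers the sparse outcome and propensity supports; the RMSE
# of the active coefficients reflects the complete-case information available
# under roughly 50% missingness.
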