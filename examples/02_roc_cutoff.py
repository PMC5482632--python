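"""ROC evaluation of a candidate transcript: AUC, Youden cutoff, dichotomization.

Draws transcript levels for 236 patients (log-normal around a high level) and
43 normals (around a low level), builds the ROC curve, reports AUC with a
DeLong 95% CI, finds the Youden-index optimal cutoff, and shows the two
dichotomization rules used downstream (fixed cutoff and median split).
"""

import numpy as np

import rbescreen as r

rng = np.random.default_rng(1)
patients = np.exp(rng.normal(np.log(50.0), 1.5, 236))
normals = np.exp(rng.normal(np.log(0.44), 1.0, 43))

res = r.roc_auc(patients, normals)
print(f"AUC = {res.auc:.3f} (DeLong 95% CI {res.auc_ci[0]:.3f}-{res.auc_ci[1]:.3f})")
print(f"Youden cutoff = {res.cutoff:.2f} (J = {res.j:.3f})")

rate = r.overexpression_rate(patients, res.cutoff)
print(f"over-expression rate above cutoff: {rate.n_above}/{rate.n_total} "
      f"= {100 * rate.fraction:.0f}%")

labels = r.dichotomize_median(patients[:168])
print(f"median split of the 168-subject cohort: "
      f"{(labels == 'low').sum()} low / {(labels == 'high').sum()} high")
# AUC is the probability a random patient level exceeds a random normal
# level; J maximizes sensitivity + specificity - 1 over all cutoffs.
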