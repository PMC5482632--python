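"""qPCR quantification: 2^-ddCt relative expression and standard curves.

Computes relative transcript levels for duplicate-well Ct measurements
against a normal-control calibrator, then builds a dilution-series standard
curve and reports the amplification efficiency and an absolute copy-number
ratio (target as % of reference).
"""

import numpy as np
import pandas as pd

import rbescreen as r

ct = pd.DataFrame(
    {
        "sample": ["patient", "patient", "normal1", "normal2"],
        "target_ct": [24.0, 26.0, 28.1, 27.9],
        "reference_ct": [20.0, 20.0, 20.0, 20.0],
        "calibrator": [False, False, True, True],
    }
)
rel = r.ddct(ct)
print(rel[["sample", "dct", "ddct", "rel_expr"]].round(3).to_string(index=False))

x = np.arange(0.0, 6.0)  # log10 plasmid copies
curve = r.std_curve(x, 38.0 - 3.50 * x)
print(f"\nstandard curve: slope {curve.slope:.2f}, "
      f"efficiency E = {curve.efficiency:.3f}, R^2 = {curve.r_squared:.4f}")

copies_target = r.ct_to_quantity(curve, 27.5)
copies_ref = r.ct_to_quantity(curve, 26.0)
print(f"copy-number ratio: {float(r.copy_ratio(copies_target, copies_ref)):.1f}%")
# rel_expr is fold change vs the mean of the calibrator samples; E = 1 would
# mean perfect doubling per cycle (slope -3.32).
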