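"""Relapse-free survival and cumulative incidence of relapse with competing death.

Simulates a 168-subject remission cohort in which a binary biomarker doubles
the relapse hazard (HR 2.5), then estimates per-group relapse-free survival
(Kaplan-Meier), the cumulative incidence of relapse treating death in
remission as a competing risk (Aalen-Johansen), and compares groups with the
log-rank test (RFS) and a Gray-type permutation test (CIR).
"""

import numpy as np

import rbescreen as r

spec = r.CohortSimSpec(
    n_subjects=168,
    log_hr={"high_level": np.log(2.5)},
    seed=5,
)
cohort = r.gen_cohort(spec)
print(cohort["event"].value_counts().to_string())

for level in (0, 1):
    sub = cohort[cohort["high_level"] == level]
    km = r.km_fit(sub)
    cif = r.cif_fit(sub)
    rfs = r.point_estimate_at(km, 60.0)
    cir = r.point_estimate_at(cif, 60.0, seed=0)
    name = "high" if level else "low"
    print(f"{name:>4}: 5-y RFS {100 * rfs.value:.0f}% "
          f"[{100 * rfs.lower:.0f}, {100 * rfs.upper:.0f}%], "
          f"5-y CIR {100 * cir.value:.0f}% "
          f"[{100 * cir.lower:.0f}, {100 * cir.upper:.0f}%] (n={len(sub)})")

chi2, p_lr = r.logrank(cohort, "high_level")
stat, p_gray = r.gray_test(cohort, "high_level", n_permutations=1999, seed=0)
print(f"log-rank (RFS): chi2 = {chi2:.2f}, P = {p_lr:.4f}")
print(f"Gray-type test (CIR): P = {p_gray:.4f}")
# A higher 5-year CIR and lower RFS in the high group reflects the doubled
# cause-specific relapse hazard; death in remission competes and is not
# counted as relapse.
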