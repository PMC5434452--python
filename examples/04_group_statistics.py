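"""Donor-level statistics on a simulated age x LPS cohort.

Draws donor cohorts from the group presets (no image rendering — the
presets carry expected densities directly), then runs the
normality-gated two-group comparison, the two-way age x LPS ANOVA with
Type II sums of squares, and the LPS response ratios.
"""

import numpy as np

from flowquant import (
    AcquisitionConfig,
    DonorRecord,
    compare_two_groups,
    percent_increase,
    response_variance_by_group,
    two_way_anova_age_lps,
)
from flowquant.synth import PRESETS, cohort_preset

config = AcquisitionConfig()
records = []
for name in ("young_control", "young_LPS", "old_control", "old_LPS"):
    n = PRESETS[name].n_group            # 16 young / 14 old donors
    for d in cohort_preset(name, n, seed=42, config=config, n_fields=6):
        truths = d.ground_truths(config)
        records.append(DonorRecord(
            d.donor_id, d.age_group, d.gender, d.treatment,
            adherent_density_mm2=float(np.mean(
                [t.n_adherent / config.field_area_mm2 for t in truths])),
            rolling_density_mm2=float(np.mean(
                [t.n_rolling / config.field_area_mm2 for t in truths])),
        ))

young = [r.adherent_density_mm2 for r in records
         if r.age_group == "young" and r.treatment == "control"]
old = [r.adherent_density_mm2 for r in records
       if r.age_group == "old" and r.treatment == "control"]
comp = compare_two_groups(old, young)
print(f"adhesion old vs young (control): {comp.test_name}, "
      f"p={comp.p_value:.3f} [{comp.significance_symbol}]")
for label, s in zip(("old", "young"), comp.group_summaries):
    print(f"  {label}: {s.mean:.1f} ± {s.sem:.1f} per mm² (n={s.n})")

anova = two_way_anova_age_lps(records)
print("two-way ANOVA on adhesion (Type II SS):")
for factor, p in anova.factor_p_values.items():
    print(f"  {factor}: F={anova.f_statistics[factor]:.2f}, p={p:.4f}")

print(f"LPS response from the printed group means: young +"
      f"{percent_increase(19, 15):.1f}%, old +{percent_increase(26, 19):.1f}%"
      f" (average {(percent_increase(19, 15) + percent_increase(26, 19)) / 2:.1f}%)")

# Per-donor LPS response ratios need paired control/LPS measurements of
# the same donor; here the pairing is modelled directly: old donors
# respond homogeneously (ratios tightly around ~1.37) while a quarter of
# young donors show a *reduced* adhesion after stimulation.
rng = np.random.default_rng(7)
ratios = {
    "old": list(rng.normal(1.37, 0.12, 14)),
    "young": list(np.concatenate([
        rng.normal(0.85, 0.08, 4),     # responders with reduced adhesion
        rng.normal(1.40, 0.25, 12),
    ])),
}
var = response_variance_by_group(ratios)
print(f"LPS response-ratio variance: young {var['young']:.2f}, "
      f"old {var['old']:.2f}")
print("A larger young-group variance means the young donors respond to "
      "LPS more heterogeneously than the old donors.")
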