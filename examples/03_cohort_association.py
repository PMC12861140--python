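"""Cohort-level association analysis with a planted pigmentation bias.

Simulates a 47-subject / 91-eye study (39 light, 52 dark eyes) with a
planted 3.1 a.u. corneal-densitometry difference, then runs the
statistical layer: mixed-effects associations (subject random intercept)
and the light-vs-dark group comparison with its bias summary.
"""

from iridens import CohortSpec, association_table, compare_groups, make_cohort
from iridens.stats import bias_summary

table, truth = make_cohort(CohortSpec(seed=1))

print(f"cohort: {table.subject_id.nunique()} subjects, {len(table)} eyes "
      f"({truth['n_light']} light / {truth['n_dark']} dark)")

assoc = association_table(table)
print("\nassociations (pooled Pearson r and mixed-model slope):")
for _, row in assoc.iterrows():
    print(f"  {row.response:>9} ~ {row.predictor:<10} "
          f"r={row.r:+.2f}  beta={row.beta:+.2f}  p={row.p_beta:.2g}")

gc = compare_groups(table)
print("\nlight vs dark group comparison (mean +/- SD, LMM p):")
for outcome in ("cd", "pct_iris", "pct_lateral", "pct_overall"):
    m, s, p = gc.means[outcome], gc.sds[outcome], gc.p_values[outcome]
    print(f"  {outcome:>12}: light {m['light']:5.1f}+/-{s['light']:.1f}  "
          f"dark {m['dark']:5.1f}+/-{s['dark']:.1f}  p={p:.2g}")

delta, rel = bias_summary(gc.means["cd"]["light"], gc.means["cd"]["dark"])
print(f"\nCD bias: {delta:.1f} a.u. = {rel:.1f}% relative overestimation "
      f"in light-iris eyes (planted {truth['delta_cd']} a.u.)")
# The recovered bias fluctuates around the planted 3.1 a.u.; the negative
# r between iris_color and the artefact percentage reproduces the
# direction of the reflection mechanism.
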