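"""Lifespan statistics: age effects, compensation models, Bayes factors.

On a 586-participant null-scenario cohort (HAROLD pattern present, no
true compensation), robust regression recovers the univariate age
effects while the age x ipsilateral interaction on RT variability stays
null -- and the JZS Bayes factor quantifies that evidence for the null.
"""

import pandas as pd

from harold import cohort, stats

spec = cohort.CohortSpec.preset("haroldnull", n_subjects=586, seed=2)
table = cohort.make_cohort_table(spec)
age = stats.age_terms(table["age"].to_numpy())

print("age effects (robust Wald F, standardized betas):")
for col, label in (("ipsi_roi", "ipsilateral mean"),
                   ("contra_roi", "contralateral mean"),
                   ("rt_sd", "RT variability")):
    res = stats.age_effect(table[col].to_numpy(), age)
    lin = res.coefficients.loc["age_lin"]
    print(f"  {label:20s} F={res.block_F:6.1f} p={res.block_p:.2g} "
          f"R2={res.r2_pct:.1f}%  linear beta={lin.beta:+.2f}")

res_int = stats.compensation_interaction(
    table["rt_sd"].to_numpy(), table["ipsi_roi"].to_numpy(), age
)
ipsi_z = (table["ipsi_roi"] - table["ipsi_roi"].mean()) / table["ipsi_roi"].std()
X_full = pd.DataFrame({
    "ipsi": ipsi_z, "age_lin": age.linear, "age_quad": age.quadratic,
    "ipsi_x_age_lin": ipsi_z * age.linear,
    "ipsi_x_age_quad": ipsi_z * age.quadratic,
})
bf01 = stats.bf_continuous_null(
    table["rt_sd"].to_numpy(),
    X_full[["ipsi", "age_lin", "age_quad"]], X_full,
)
print(f"\nage x ipsilateral interaction on RT variability: "
      f"F={res_int.block_F:.2f}, p={res_int.block_p:.2f}")
print(f"BF01 for dropping the interaction: {bf01:.1f} "
      f"({stats.interpret_bf(bf01)} evidence for the null)")
print("\nThe compensation account predicts this interaction; in the null "
      "scenario the Bayes factor correctly favors its absence.")
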