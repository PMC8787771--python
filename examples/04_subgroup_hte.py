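"""Hierarchical subgroup analysis: norepinephrine-dose quintile groups.

Norepinephrine dose is zero-inflated (non-users are an exact point mass at
zero), so the first subgroup is all non-users and the positive doses split
into four near-equal tie-respecting groups.  Subgroup treatment effects are
partially pooled: each group's log-OR is beta + b_g with b_g ~ Normal(0,
sigma_b), shrinking noisy groups towards the overall effect.
"""

from bayeshte import (GeneratorConfig, ModelSpec, fit_subgroup_hte,
                      generate_trial, missingness_gate, most_common_profile,
                      quintile_subgroups, subgroup_effect_table)

dataset = generate_trial(GeneratorConfig(seed=1))
gated, _ = missingness_gate(dataset, ["dead_90d", "allocation", "copd", "haem",
                                      "site_id", "norepi_dose"])
scheme = quintile_subgroups(gated.df["norepi_dose"], zero_mass_group=True,
                            variable="norepi_dose")
print("subgroup ranges and sizes:")
print(scheme.to_frame().to_string(index=False))

spec = ModelSpec(kind="subgroup", chains=2, warmup=300, draws=800, seed=3)
draws = fit_subgroup_hte(gated, scheme, spec)
profile = most_common_profile(gated, draws)
_, table = subgroup_effect_table(draws, profile)
cols = ["group", "n", "rr_median", "rr_cri_low", "rr_cri_high", "rd_pct_median"]
print("\nper-subgroup adjusted effects (RR and RD in percentage points):")
print(table[cols].round(3).to_string(index=False))
print("\nUnder the null simulation all subgroup RRs should sit near 1, with")
print("partial pooling keeping the small-group intervals from exploding.")
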