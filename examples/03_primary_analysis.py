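"""Fit the primary Bayesian analysis and standardize the posterior to RR/RD.

The model is an adjusted logistic regression (treatment + COPD +
haematological malignancy + partially pooled site intercepts) with the weak
prior on the treatment log-OR.  Event probabilities are standardized at the
most common covariate profile; every effect measure is computed per draw.
Reduced draws keep the example quick; the published configuration is
4 chains x (5000 + 5000).
"""

import numpy as np

from bayeshte import (GeneratorConfig, ModelSpec, diagnostics, effect_summary,
                      fit_primary, generate_trial, missingness_gate,
                      most_common_profile, standardized_event_probs)

dataset = generate_trial(GeneratorConfig(seed=1))
gated, log = missingness_gate(dataset, ["dead_90d", "allocation", "copd",
                                        "haem", "site_id"])
print(f"complete cases: {log['n_complete']} of {log['n_total']}")

spec = ModelSpec(kind="primary", chains=2, warmup=400, draws=1000, seed=2)
draws = fit_primary(gated, spec)
rep = diagnostics(draws)
print(f"diagnostics acceptable: {rep.acceptable} "
      f"(max R-hat {np.nanmax(rep.table['rhat']):.3f}, "
      f"divergences {rep.divergences})")

profile = most_common_profile(gated, draws)
p0, p1 = standardized_event_probs(draws, profile)
s = effect_summary(p0, p1, n_patients=gated.n)
print(f"\nadjusted mortality, lower target : {100*s.p1[0]:.1f}% "
      f"(95% CrI {100*s.p1[1]:.1f}-{100*s.p1[2]:.1f})")
print(f"adjusted mortality, higher target: {100*s.p0[0]:.1f}% "
      f"(95% CrI {100*s.p0[1]:.1f}-{100*s.p0[2]:.1f})")
print(f"RR {s.rr[0]:.2f} (95% CrI {s.rr[1]:.2f}-{s.rr[2]:.2f});  "
      f"RD {s.rd[0]:+.1f}pp (95% CrI {s.rd[1]:+.1f} to {s.rd[2]:+.1f})")
print(f"P(RR < 1.00) = {100*s.prob_rr_below[1.0]:.1f}%   "
      f"P(RR < 0.80) = {100*s.prob_rr_below[0.80]:.2f}%")
print("\nThe cohort is simulated with a null treatment effect, so RR should")
print("hover near 1 and P(RR<0.80) -- a 20% mortality reduction -- near zero.")
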