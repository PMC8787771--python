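"""Generate the default synthetic trial cohort and inspect its marginals.

The generator emulates a ~2900-patient two-arm ICU oxygenation trial:
1:1 allocation stratified by site/COPD/haematological malignancy, severity
markers moment-matched to the published baseline table, and a configurable
true treatment effect (zero by default, mirroring the near-null trial result).
"""

from bayeshte import GeneratorConfig, generate_trial
from bayeshte.synthetic import empirical_summary

dataset = generate_trial(GeneratorConfig(seed=1))
print(f"generated {dataset.n} patients")
print(empirical_summary(dataset).round(3).to_string())
print("\nMedians should sit near the emulation targets: SOFA 8, lactate 1.8 mM,")
print("PaO2:FiO2 15.8 kPa, ~55% vasopressor use, ~42-43% 90-day mortality,")
print("with ~50% of patients allocated to the lower oxygenation target.")

dataset.to_csv("cohort.csv")
print("\nwrote cohort.csv (fixed column order, missing values as empty fields)")
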