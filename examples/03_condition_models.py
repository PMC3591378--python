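"""Body-condition comparison of two groups via nested allometric models.

Simulates length–mass data for two rearing groups whose allometries differ
in both intercept and slope, fits the four grouped log10–log10 regression
models, and ranks them by AICc.  Over the narrow length range of juvenile
fish the three group-structured models can mimic one another, so they
share the Akaike weight — but the shared-line model should be decisively
rejected, which is the substantive conclusion: the groups differ in body
condition.  The length distributions are also compared with the
Bartlett-gated location test.
"""

from gsikit import (
    ConditionDesign,
    GroupConditionParams,
    compare_condition,
    compare_lengths,
    simulate_condition,
)
from gsikit.condition import comparison_table

design = ConditionDesign(
    groups={
        "Black Lake residents": GroupConditionParams(
            intercept=-5.00, slope=3.02, resid_sd=0.035,
            length_mean=69.7, length_sd=5.4, n=250,
        ),
        "Chignik Lake residents": GroupConditionParams(
            intercept=-5.20, slope=3.06, resid_sd=0.045,
            length_mean=65.1, length_sd=7.9, n=250,
        ),
    },
    seed=11,
)
data = simulate_condition(design)

fits = compare_condition(data)
print("Model ranking (log10 mass ~ log10 length, AICc ascending):")
print(comparison_table(fits).to_string(index=False))
best = fits[0]
grouped_weight = sum(f.weight for f in fits if f.model_id != "M_shared")
print(
    f"\nBest model: {best.model_id} (Akaike weight {best.weight:.2f}, the "
    "estimated\nprobability it is the best of the four candidates). The "
    "group-structured\nmodels jointly carry weight "
    f"{grouped_weight:.2f}, so a single shared length-mass\nline is ruled "
    "out: the groups differ in mass-at-length, i.e. in body\ncondition."
)

lengths = compare_lengths(data, alpha=0.05)
print(
    f"\nLength comparison: Bartlett p = {lengths.bartlett_p:.3g} -> "
    f"{lengths.chosen_test}; statistic = {lengths.statistic:.2f}, "
    f"df = {lengths.df}, p = {lengths.p_value:.3g}."
)
print(
    "(Heteroscedastic lengths route to the rank test; a small p says the "
    "groups'\nlength distributions differ.)"
)
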