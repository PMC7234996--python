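"""Why the phylogenetic correction matters: type-I error under the null.

Generates null cohorts (no clade effect) on Yule trees where the factor is a
monophyletic clade, runs the full stratified pipeline, and contrasts the
PI-KW rejection rate with the conventional chi-square KW rate. Shared
ancestry makes the naive test reject wildly too often; the PI test stays
near the nominal 5%.
"""

from pikw.experiments import null_rejection_rates

# 60 null datasets keeps this demo quick; the test suite runs 200
rates = null_rejection_rates(n_datasets=60, n_tips=80, n_sims=500, seed0=0)
print(f"strata tested:          {rates.n_tests}")
print(f"PI-KW rejection rate:   {rates.pi_rate:.3f}   (nominal 0.05)")
print(f"naive KW rejection rate: {rates.naive_rate:.3f}")
print(
    "\nEvery rejection here is a false positive: the trait evolved by pure\n"
    "Brownian motion with no clade effect. The conventional test mistakes\n"
    "phylogenetic autocorrelation for a factor effect."
)
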