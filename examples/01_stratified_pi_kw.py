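"""Stratified PI Kruskal-Wallis analysis on a synthetic cohort.

Builds an 80-species cohort whose KEAP1-nonfunctional clade carries a 3-SD
upward shift in the MS-BMR-like trait, stratifies by the (independent)
lifespan-like trait, screens each stratum with a conventional KW test, and
judges significance against Brownian-motion empirical nulls on the
stratum-pruned tree.
"""

from pikw.cohort import assign_strata
from pikw.pi_kw import run_pipeline
from pikw.synthetic_data import SynthConfig, make_dataset

cfg = SynthConfig(n_tips=80, clade_shift=3.0, seed=42)
tree, table, truth = make_dataset(cfg)
print(f"cohort: {len(table)} species, "
      f"{(table.keap1_functional == 0).sum()} in the shifted clade")

assignment = assign_strata(table, "max_lifespan", (20.0,))
summary, results = run_pipeline(
    tree, table, "ms_bmr", assignment, n_sims=1000, seed=42
)
cols = ["stratum", "n0", "n1", "H", "chisq_p", "threshold_95",
        "empirical_p_add_one", "significant"]
print(summary[cols].round(4).to_string(index=False))
print(
    "\nPer stratum: H is the observed Kruskal-Wallis statistic for MS-BMR by\n"
    "KEAP1 status; threshold_95 is the 95th percentile of 1000 simulated null\n"
    "H values on the stratum's pruned tree (well above the chi-square 3.841\n"
    "because the factor is clade-structured); empirical_p is the add-one\n"
    "upper-tail proportion. 'significant' requires passing the conventional\n"
    "screen AND exceeding the phylogenetic threshold."
)
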