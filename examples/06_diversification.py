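"""Species richness and symbiosis: family models and sister contrasts.

Plants a four-fold richness advantage for families with obligate
symbionts, then recovers it with (a) the joint symbiosis + richness
mixed model, (b) the sister-pair Poisson model, (c) the log2 richness-
ratio analysis on pairs that differ in symbiosis.
"""

import numpy as np
import pandas as pd

from symphy import diversification as dv
from symphy import synth
from symphy.pglmm import ChainSettings

tree = synth.sim_tree(140, seed=31)
rng = np.random.default_rng(32)
n_sampled = 1 + rng.poisson(3, tree.n_tips)
p_ob = rng.beta(0.4, 0.8, tree.n_tips)  # continuous prevalence across families
rich, truth = synth.sim_richness(tree, p_ob,
                                 base_log_rate=3.0,
                                 trait_effect=np.log(4.0),
                                 age_effect=0.4, clade_sd=0.4, seed=33)
table = pd.DataFrame({
    "family": tree.tip_labels,
    "n_sampled": n_sampled,
    "n_obligate": rng.binomial(n_sampled, p_ob),
    "species_richness": rich["species_richness"],
    "family_age": rich["family_age"],
    "metabolism": rich["metabolism"],
    "feeding_niche": rng.choice(["herbivore", "omnivore"], tree.n_tips),
})
print(f"planted: richness x{np.exp(truth['trait_effect']):.0f} for "
      f"obligate families, positive age effect")

res = dv.richness_model(table, tree,
                        ChainSettings(n_iter=4000, burnin=1500, thin=4,
                                      seed=34))
r = res["phylo_correlation"]
print(f"phylo correlation symbiosis-richness: mode {r.mode:.2f}, "
      f"CI ({r.ci_low:.2f}, {r.ci_high:.2f}), pMCMC {r.pmcmc:.3f}")

pairs = dv.assemble_sister_pairs(tree, table)
print(f"\n{len(pairs)} sister pairs (cherries) extracted")
sr = dv.sister_richness_model(pairs, tree,
                              ChainSettings(n_iter=3000, burnin=1000, thin=4,
                                            seed=35))
s = sr["pct_obligate_effect"]
print(f"sister model, %-obligate effect on log richness: mode {s.mode:.2f}, "
      f"CI ({s.ci_low:.2f}, {s.ci_high:.2f}), pMCMC {s.pmcmc:.3f}")

try:
    lr = dv.sister_log2_analysis(pairs, tree,
                                 ChainSettings(n_iter=3000, burnin=1000,
                                               thin=4, seed=36))
    d = lr["pct_diff_effect"]
    print(f"log2-ratio model, %-difference effect: mode {d.mode:.2f}, "
          f"CI ({d.ci_low:.2f}, {d.ci_high:.2f}), pMCMC {d.pmcmc:.3f}")
    mean_ratio = lr["data"]["log2_ratio"].mean()
    print(f"mean log2 richness ratio (higher-% member as numerator): "
          f"{mean_ratio:.2f}")
except ValueError as e:
    print(f"log2 analysis skipped: {e}")
print()
print("Positive estimates across all three designs indicate that lineages "
      "richer in obligate symbionts carry more species, at matched clade "
      "age in the sister comparisons.")
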