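"""Did low B vitamins precede obligate symbiosis, or follow it?

Simulates symbiosis as a two-state chain and a B5 level that declines
gradually only *after* lineages become obligate, then runs the full
before/after pipeline: binomial mixed model -> ancestral node states ->
nutrient reconstruction -> resampled four-way classification ->
category contrasts pooled across resamples.
"""

import numpy as np
import pandas as pd

from symphy import mk, synth, transitions

tree = synth.sim_tree(80, seed=41)
Q = mk.RateMatrix.from_rates(["non", "ob"], [0.0015, 0.0005],
                             "all_rates_different")
sim = synth.sim_mk_trait(tree, Q, seed=46, root_state=0)
tip_states = np.array([sim["tip_states"][l] for l in tree.tip_labels])
height = tree.tip_depths().max()
b5, _ = synth.sim_state_linked_nutrient(tree, sim["node_states"],
                                        state_effect=-3.5,
                                        saturation=0.4 * height, seed=43)
b9, _ = synth.sim_state_linked_nutrient(tree, sim["node_states"],
                                        state_effect=-3.5,
                                        saturation=0.4 * height, seed=44)
rng = np.random.default_rng(45)
n_sampled = 1 + rng.poisson(3, tree.n_tips)
table = pd.DataFrame({
    "family": tree.tip_labels,
    "n_sampled": n_sampled,
    "n_obligate": np.where(tip_states == 1, n_sampled, 0),
    "B5": b5["value"],
    "B9": b9["value"],
})
true_counts = mk.count_state_transitions(tree, sim["node_states"], {1})
print(f"simulated: {true_counts['n_origins']} origins, "
      f"{true_counts['n_losses']} losses; B5 declines only after origins")

res = transitions.transition_pipeline(tree, table, n_resamples=20, seed=47)
print(f"\npooled contrasts ({res.n_resamples} resamples x "
      f"{res.draws_per_resample} draws each):")
print(res.contrasts.to_string(index=False,
                              float_format=lambda x: f"{x:.3f}"))
print("\nmean node counts per category:")
print(res.category_counts[list(transitions.CATEGORIES)].mean().round(1)
      .to_string())
print()
print("The expected signature of 'symbionts first, diet later': the "
      "maintenance contrast (ObToOb - NonToNon) is clearly negative while "
      "the origin contrast (NonToOb - NonToNon) stays near zero - ancestors "
      "did not already sit on B-vitamin-poor diets before recruiting "
      "symbionts.")
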