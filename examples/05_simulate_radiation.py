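"""Forward-time radiation simulation with full ground truth.

Runs the study-scale simulator (50 tips, 11 regions with staggered
island emergence, low anagenetic rates, equal founder and within-island
speciation rates), then shows the pieces every analysis stage consumes:
the dated tree, tip ranges, the true per-node event classes, a trait
matrix with a divergence kick at within-island nodes, and a simulated
co-occurrence dataset.
"""

import islandrad as ir

radiation = ir.simulate_radiation(ir.study_sim_config(seed=7))
tree = radiation.tree
geo = radiation.config.geography
print(f"tree: {tree.n_tips} tips, root age {tree.root_age:.2f} myr")
n_founder = sum(k == "founder" for k in radiation.node_truth.values())
print(f"true cladogenetic events: {n_founder} founder, "
      f"{len(radiation.node_truth) - n_founder} within-island "
      f"(founder fraction {radiation.true_founder_fraction:.2f})")
sizes = sorted(len(r) for r in radiation.tip_ranges.values())
print(f"tip range sizes: min {sizes[0]}, max {sizes[-1]}\n")

intra = {n for n, k in radiation.node_truth.items() if k == "within_island"}
traits = ir.simulate_traits(tree, intra, ir.TraitConfig(delta=1.0, seed=8))
print(f"trait matrix: {traits.values.shape[0]} taxa x "
      f"{traits.values.shape[1]} characters "
      f"({len(traits.columns_of_class('morphological'))} morphological, "
      f"{len(traits.columns_of_class('ecological'))} ecological)")
node = sorted(intra)[0]
print(f"example morphological RED at within-island node {node}: "
      f"{ir.node_red(tree, node, traits.subset('morphological')):.2f}\n")

cooc = ir.simulate_cooccurrence(radiation.tip_ranges, geo,
                                co_prob=0.6, hybrid_prob=0.3, seed=9)
for island, r in sorted(ir.island_rates(cooc).items()):
    if r.cooccurrence_rate is not None:
        print(f"  {island}: {r.n_taxa} taxa, co-occurrence "
              f"{100 * r.cooccurrence_rate:.0f} %, hybridization "
              f"{100 * r.hybridization_rate:.0f} %")
print("\nSame seed -> byte-identical outputs; the event log replays to "
      "the exact tip ranges.")
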