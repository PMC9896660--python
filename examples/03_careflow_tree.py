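"""CareFlow prefix trees: frequent pathways and stratified node tests.

Mines the tree rooted at the no-impairment state M_0000, prunes
pathways followed by fewer than 10 patients, and stratifies the tree on
age at onset (cut at 55 years) to ask, node by node, whether older
patients are over-represented on any pathway.
"""

from alsflow import (
    GeneratorConfig,
    cfm_to_dot,
    edge_percentages,
    generate,
    mine_cfm,
    prune_cfm,
    stratify_cfm,
)

log, _ = generate(GeneratorConfig.trial_like(800, seed=11, death_age_effect=0.5))

tree = prune_cfm(mine_cfm(log, "M_0000"), min_support=10)
pct = edge_percentages(tree)
print(f"root M_0000 reached by {tree.root.support} of {tree.population_size} patients")
for child in tree.root.children[:4]:
    p_parent, p_pop = pct[child.node_id]
    print(f"  -> {child.activity}: {child.support} patients "
          f"({100 * p_parent:.0f}% of parent, {100 * p_pop:.0f}% of population), "
          f"median {child.median_time:.0f} days from root")

strat = stratify_cfm(log, "M_0000", "age_at_onset", 55, alpha=0.05, min_support=10)
flagged = [(node, strat.stats[node.node_id]) for node in strat.tree.nodes()
           if strat.stats[node.node_id].significant]
print(f"\nage-stratified tree: {len(flagged)} node(s) with p < 0.05 "
      f"({strat.level_a} vs {strat.level_b})")
for node, ns in flagged[:5]:
    print(f"  {' > '.join(node.path)}: {ns.support_a}/{ns.support_b}, "
          f"ratio {ns.ratio:.2f}, {ns.test} p = {ns.p_value:.2g}")
# strata are ordered alphabetically, so level A is "high": a ratio above 1
# means the pathway is relatively more travelled by the older-onset
# stratum, here by construction of the age effect on death

dot = cfm_to_dot(strat)
yellow = dot.count('fillcolor="yellow"')
print(f"\nDOT output: {dot.count('->')} edges, {yellow} node(s) highlighted yellow")
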