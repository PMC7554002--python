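"""Simulate a screener cohort and derive an ordinal risk scale from it.

Grows a mean-risk regression tree on the admissible items (plus the
nine-item depression sum score), collapses the terminal nodes into at most
seven ordered groups by exact weighted 1-D k-means, and prunes over-branched
splits.  Prints the tree's splits and the per-group statistics: each group's
size and its mean clinician danger-to-self rating (0-4), which must increase
strictly with the group label.
"""

from risktree import default_config, simulate_frame
from risktree.pipeline import derive_algorithm

config = default_config(n=20_000, seed=1)
sim = simulate_frame(config)
algo = derive_algorithm(sim.frame, config.dictionary, dss=config.dss)

print(f"terminal nodes: {algo.tree.n_leaves()}, groups: {algo.k}")
print("splits used:")
for node in sorted(algo.tree.internal_nodes(), key=lambda n: n.node_id):
    print(f"  node {node.node_id} (depth {node.depth}): {node.item} <= {node.threshold}")
print("group statistics (label, n, mean rating):")
for s in algo.group_stats:
    print(f"  level {s.label}: n={s.n:8.0f}  mean danger-to-self={s.mean_risk:.3f}")
print(
    "\nHigher labels concentrate higher clinician-rated risk; the strictly"
    "\nincreasing means are what make the 0..6 labels an ordinal scale."
)
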