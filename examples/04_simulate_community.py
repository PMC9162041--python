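"""Tour of the synthetic-data generator.

Shows the pieces the simulation studies are built from: a random rooted
phylogeny, zero-inflated log-normal abundances coupled by a Gaussian
copula, multinomial read counts at a log-normal depth, and k-medoids
clusters of leaves on the cophenetic distance.
"""

import numpy as np

from miaf import CommunityModel, cluster_otus, simulate_abundances, simulate_tree

q, n = 30, 200
tree = simulate_tree(q, seed=100)
print(f"tree: {q} leaves, {tree.n_nodes} nodes, "
      f"{tree.internal_nonroot().size} internal non-root nodes")
print("newick prefix:", tree.to_newick()[:70], "...")

model = CommunityModel.default(q, seed=101)
X, reads = simulate_abundances(model, n, seed=102)
print(f"\nabsolute abundances X: {X.shape}, "
      f"zero fraction = {np.mean(X == 0):.2f} "
      f"(model mean pi = {model.pi.mean():.2f})")
depth = reads.sum(axis=1)
print(f"read counts: median depth = {np.median(depth):.0f}, "
      f"range {depth.min()}..{depth.max()}")

labels = cluster_otus(tree, k=4)
sizes = np.bincount(labels)
print(f"\nk-medoids clusters on cophenetic distance: sizes = {sizes.tolist()}")
print("\nThe test is validated against data from this generator: each")
print("replicate draws a fresh community from the same fixed tree and")
print("marginal parameters, which mimics resampling subjects from one")
print("underlying microbial population.")
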