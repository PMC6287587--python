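"""Evolve bone-contact tables on a random tree and watch similarity decay.

Simulates eight taxa whose 50 bone-pair contacts evolve by presence
toggles, spatial-relation switches and one-step suture-depth moves, then
prints the similarity of each tip pair against its path length on the
tree.  More path length means more accumulated events, so similarity
should fall as path length grows.
"""

import itertools

import numpy as np

from sutura import ContactEvolutionModel, random_tree, similarity_matrix, simulate_tables

tree = random_tree(8, seed=42)
model = ContactEvolutionModel(
    rate_spatial_switch=0.3, rate_depth_step=0.3, rate_gain_loss=0.1,
    n_pairs=50, seed=42,
)
tips, ancestor = simulate_tables(tree, model)
matrix = similarity_matrix(tips)
paths = tree.leaf_path_lengths()

rows = []
for i, j in itertools.combinations(range(len(matrix.taxa)), 2):
    a, b = matrix.taxa[i], matrix.taxa[j]
    if np.isnan(matrix.values[i, j]):
        continue
    rows.append((paths[frozenset((a, b))], a, b, int(matrix.values[i, j])))

print("path length   pair        similarity")
for d, a, b, pct in sorted(rows):
    print(f"{d:10.2f}    {a:>3s} - {b:<3s}   {pct:3d}%")
print("\nShorter paths keep higher similarity: the statistic tracks the tree.")
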