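"""Enumerate the SPR neighborhood of a small tree and extract move features.

Builds a 7-taxon tree, lists every subtree-prune-and-regraft rearrangement
(one per distinct neighbor topology), and prints the 19 predictors for the
first few moves.
"""
import numpy as np

from sprank import FEATURE_NAMES, batch_features, enumerate_spr_moves, spr_neighborhood_size
from sprank.simulate import sample_tree

tree = sample_tree(7, seed=1)
moves = enumerate_spr_moves(tree)
print(f"7-taxon tree: {len(moves)} SPR neighbors "
      f"(formula 2(n-3)(2n-7) = {spr_neighborhood_size(7)})")

features = batch_features(tree, moves)
print(f"feature matrix: {features.shape[0]} moves x {features.shape[1]} features\n")
print("first three moves:")
for i in range(3):
    m = moves[i]
    print(f"  move {i}: prune branch {m.prune_branch} (side {m.prune_side}), "
          f"regraft onto branch {m.regraft_branch}")
    for name, value in zip(FEATURE_NAMES, features[i]):
        print(f"    {name:>15s} = {value:.4g}")

# features 1-2 describe the starting tree, so they are identical across moves
assert np.ptp(features[:, 0]) == 0 and np.ptp(features[:, 1]) == 0
print("\ntotal_bl and longest_branch are move-invariant, as expected: they "
      "describe the starting tree, not the rearrangement.")
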