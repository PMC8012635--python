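"""Train the random-forest move ranker on a small corpus and rank moves.

Builds a labelled corpus of six synthetic datasets, trains the forest on
five of them, and checks how well the predicted ranking of the held-out
dataset's SPR moves matches the true likelihood ranking.
"""
import numpy as np

from sprank import FEATURE_NAMES, rank_moves, spearman_rho, train
from sprank.simulate import make_corpus

corpus = make_corpus(6, taxa_range=(7, 10), sites_range=(200, 300), seed=11)
frame = corpus.to_frame()
held_out = corpus.datasets[0]
train_frame = frame[frame.dataset_id != held_out.dataset_id]

model = train(
    train_frame[list(FEATURE_NAMES)].to_numpy(),
    train_frame["transformed_target"].to_numpy(),
    seed=0,
)
ranking = rank_moves(model, held_out.features, held_out.ll_start)

true_delta = held_out.ll_neighbors - held_out.ll_start
rho = spearman_rho(true_delta, ranking.sort_values("move_id")["predicted_delta_ll"].to_numpy())
top = ranking.iloc[0]
true_rank_of_top = int(np.sum(true_delta > true_delta[int(top.move_id)])) + 1

print(f"held-out dataset {held_out.dataset_id}: {len(held_out.moves)} SPR moves")
print(f"Spearman rho between predicted and true move ranking: {rho:.3f}")
print(f"top-predicted move {int(top.move_id)}: predicted dLL {top.predicted_delta_ll:+.2f}, "
      f"true dLL {true_delta[int(top.move_id)]:+.2f} "
      f"(true rank {true_rank_of_top} of {len(true_delta)})")
print("rho near 1 means the cheap 19-feature forest orders candidate "
      "rearrangements almost as well as full likelihood optimization would.")
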