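"""Synthetic trees, alignments and fully labelled training corpora.

This module stands in for an empirical phylogeny collection: it samples
random binary trees and GTR+I+G parameters, evolves nucleotide alignments
along them, and runs the full labelling pipeline (NJ starting tree, model
fit, SPR enumeration, per-neighbor likelihood optimization, feature
extraction) to produce training corpora for the move ranker.

Default corpus conditions emulate small-to-moderate empirical datasets:
7-16 taxa, 300-500 sites, exponential branch lengths with mean 0.1
substitutions/site, exchangeabilities lognormal(0, 0.5^2), base frequencies
Dirichlet(5,5,5,5), gamma shape uniform on (0.5, 2) and invariant
proportion uniform on (0, 0.3).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, batch_features
from .learner import transform_target
from .likelihood import (
    SubstitutionModel,
    log_likelihood,
    optimize_branch_lengths,
    optimize_model,
    score_all_neighbors,
)
from .spr import SPRMove, enumerate_spr_moves
from .tree import Alignment, PhyloTree, build_starting_tree

logger = logging.getLogger(__name__)

__all__ = [
    "sample_tree",
    "sample_gtr_model",
    "simulate_alignment",
    "LabeledDataset",
    "Corpus",
    "make_corpus",
]


def sample_tree(
    n_taxa: int,
    seed: int | np.random.Generator,
    mean_branch_length: float = 0.1,
    shape: str = "uniform",
) -> PhyloTree:
    """Random binary unrooted tree with exponential branch lengths.

    ``shape='uniform'`` draws uniformly over labelled topologies (each new
    leaf attaches to a uniformly chosen branch); ``shape='yule'`` splits a
    uniformly chosen existing *leaf* instead, giving Yule-like shapes.
    Leaves are labelled t01, t02, ...
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if shape not in ("uniform", "yule"):
        raise ValueError(f"unknown shape {shape!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = [f"t{i + 1:02d}" for i in range(n_taxa)]
    t = PhyloTree()
    center = t._new_node()
    for lab in labels[:3]:
        t._add_branch(center, t._new_node(lab), 1.0)
    for lab in labels[3:]:
        if shape == "uniform":
            bid = int(rng.choice(t.branch_ids))
        else:
            leaf_nodes = sorted(t.leaf_nodes)
            leaf = int(rng.choice(leaf_nodes))
            bid = next(iter(t.neighbors(leaf).values()))
        u, v = t.branch_endpoints(bid)
        t._remove_branch(bid)
        mid = t._new_node()
        t._add_branch(u, mid, 1.0)
        t._add_branch(mid, v, 1.0)
        t._add_branch(mid, t._new_node(lab), 1.0)
    for bid in t.branch_ids:
        t.set_branch_length(bid, float(rng.exponential(mean_branch_length)))
    t.renumber()
    t.validate()
    return t


def sample_gtr_model(
    seed: int | np.random.Generator, n_cats: int = 4
) -> SubstitutionModel:
    """Random GTR+I+G parameters spanning realistic empirical ranges."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rates = np.append(np.exp(rng.normal(0.0, 0.5, size=5)), 1.0)
    freqs = rng.dirichlet(np.full(4, 5.0))
    freqs = np.maximum(freqs, 1e-3)
    freqs = freqs / freqs.sum()
    alpha = float(rng.uniform(0.5, 2.0))
    p_inv = float(rng.uniform(0.0, 0.3))
    return SubstitutionModel(rates=rates, freqs=freqs, p_inv=p_inv, alpha=alpha, n_cats=n_cats)


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int | np.random.Generator,
) -> Alignment:
    """Evolve *n_sites* nucleotide sites along *tree* under *model*.

    Root states are drawn from the stationary frequencies; each site is
    invariant with probability ``p_inv`` and otherwise carries a continuous
    gamma rate rescaled by ``1/(1 - p_inv)``, mirroring the likelihood
    model's rate convention.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    site_rates = np.ones(n_sites)
    if model.alpha is not None:
        site_rates = rng.gamma(model.alpha, 1.0 / model.alpha, size=n_sites)
    if model.p_inv > 0:
        invariant = rng.random(n_sites) < model.p_inv
        site_rates = np.where(invariant, 0.0, site_rates / (1.0 - model.p_inv))

    root = min(n for n in tree.nodes if not tree.is_leaf(n))
    states = {root: rng.choice(4, size=n_sites, p=model.freqs)}
    order = list(tree.traverse_from(root))
    unique_rates, inverse = np.unique(site_rates, return_inverse=True)
    for node, parent, bid in order:
        if parent is None:
            continue
        t = tree.branch_length(bid)
        parent_states = states[parent]
        child = np.empty(n_sites, dtype=np.int64)
        for ri, rate in enumerate(unique_rates):
            sel = inverse == ri
            if not np.any(sel):
                continue
            if rate == 0.0 or t == 0.0:
                child[sel] = parent_states[sel]
                continue
            p = model.transition_matrix(t, rate)
            p = p / p.sum(axis=1, keepdims=True)
            sub = parent_states[sel]
            u = rng.random(sub.shape[0])
            cum = np.cumsum(p, axis=1)[sub]
            child[sel] = (u[:, None] > cum).sum(axis=1)
        states[node] = child

    bases = np.array(list("ACGT"))
    seqs = {
        label: "".join(bases[states[nid]]) for nid, label in tree.leaf_nodes.items()
    }
    return Alignment(seqs)


@dataclass
class LabeledDataset:
    """One synthetic dataset with its fully labelled SPR neighborhood."""

    dataset_id: str
    alignment: Alignment
    true_tree: PhyloTree
    start_tree: PhyloTree  # NJ topology with optimized branch lengths
    model: SubstitutionModel  # parameters fit on the starting tree
    ll_start: float
    moves: list[SPRMove]
    features: np.ndarray  # (n_moves, 19)
    ll_neighbors: np.ndarray

    @property
    def targets(self) -> np.ndarray:
        return (self.ll_neighbors - self.ll_start) / self.ll_start

    @property
    def transformed_targets(self) -> np.ndarray:
        return transform_target(self.targets)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(FEATURE_NAMES))
        df.insert(0, "move_id", np.arange(len(self.moves)))
        df.insert(0, "dataset_id", self.dataset_id)
        df["ll_start"] = self.ll_start
        df["ll_neighbor"] = self.ll_neighbors
        df["target"] = self.targets
        df["transformed_target"] = self.transformed_targets
        return df


@dataclass
class Corpus:
    """A collection of labelled datasets plus the manifest that regenerates it."""

    datasets: list[LabeledDataset]
    manifest: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([d.to_frame() for d in self.datasets], ignore_index=True)

    @property
    def n_examples(self) -> int:
        return sum(len(d.moves) for d in self.datasets)


def label_dataset(
    dataset_id: str,
    aln: Alignment,
    true_tree: PhyloTree,
    label_model: str = "gtr",
    neighbor_tol: float = 1e-3,
    neighbor_max_sweeps: int = 8,
) -> LabeledDataset:
    """Run the labelling pipeline for one alignment.

    Builds the NJ starting tree, fits (or fixes, for JC) the substitution
    model on it, optimizes its branch lengths, enumerates all SPR moves, and
    computes each neighbor's optimized log-likelihood with the model held
    fixed.
    """
    start = build_starting_tree(aln)
    if label_model == "gtr":
        model = optimize_model(start, aln)
    elif label_model == "jc":
        model = SubstitutionModel.jc()
    else:
        raise ValueError(f"unknown label model {label_model!r}")
    res = optimize_branch_lengths(start, aln, model, tol=1e-4, max_sweeps=10)
    start_opt, ll_start = res.tree, res.log_likelihood
    moves = enumerate_spr_moves(start_opt)
    feats = batch_features(start_opt, moves)
    scored = score_all_neighbors(
        start_opt, aln, model, moves, tol=neighbor_tol, max_sweeps=neighbor_max_sweeps
    )
    ll_neighbors = np.array([ll for _mv, ll in scored])
    return LabeledDataset(
        dataset_id=dataset_id,
        alignment=aln,
        true_tree=true_tree,
        start_tree=start_opt,
        model=model,
        ll_start=ll_start,
        moves=moves,
        features=feats,
        ll_neighbors=ll_neighbors,
    )


def make_corpus(
    n_datasets: int,
    taxa_range: tuple[int, int] = (7, 16),
    sites_range: tuple[int, int] = (300, 500),
    model_family: str = "gtr",
    label_model: str | None = None,
    seed: int = 1,
    mean_branch_length: float = 0.1,
) -> Corpus:
    """Generate a fully labelled synthetic corpus.

    ``model_family`` selects the *simulation* model ('gtr' for GTR+I+G with
    randomly drawn parameters, 'jc' for Jukes-Cantor); ``label_model``
    selects the model used for likelihood labelling (defaults to the
    simulation family).  Deterministic given *seed*; the per-dataset seeds
    are recorded in the manifest.
    """
    if label_model is None:
        label_model = model_family
    rng = np.random.default_rng(seed)
    datasets = []
    manifest = {
        "n_datasets": n_datasets,
        "taxa_range": list(taxa_range),
        "sites_range": list(sites_range),
        "model_family": model_family,
        "label_model": label_model,
        "seed": seed,
        "mean_branch_length": mean_branch_length,
        "datasets": [],
    }
    for i in range(n_datasets):
        ds_seed = int(rng.integers(0, 2**31 - 1))
        ds_rng = np.random.default_rng(ds_seed)
        n_taxa = int(ds_rng.integers(taxa_range[0], taxa_range[1] + 1))
        n_sites = int(ds_rng.integers(sites_range[0], sites_range[1] + 1))
        if model_family == "gtr":
            sim_model = sample_gtr_model(ds_rng)
        elif model_family == "jc":
            sim_model = SubstitutionModel.jc()
        else:
            raise ValueError(f"unknown model family {model_family!r}")
        true_tree = sample_tree(n_taxa, ds_rng, mean_branch_length=mean_branch_length)
        aln = simulate_alignment(true_tree, sim_model, n_sites, ds_rng)
        dataset_id = f"d{i:03d}"
        ds = label_dataset(dataset_id, aln, true_tree, label_model=label_model)
        datasets.append(ds)
        manifest["datasets"].append(
            {"dataset_id": dataset_id, "seed": ds_seed, "n_taxa": n_taxa, "n_sites": n_sites}
        )
        logger.info(
            "labelled %s: %d taxa, %d sites, %d moves", dataset_id, n_taxa, n_sites, len(ds.moves)
        )
    return Corpus(datasets=datasets, manifest=manifest)
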