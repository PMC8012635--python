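import numpy as np
import pytest

from sprank.simulate import make_corpus

# shared conditions of the synthetic study corpus (see docs/methods.md)
CORPUS_SEED = 7
CORPUS_N_DATASETS = 20


@pytest.fixture(scope="session")
def corpus_gtr():
    """Synthetic corpus labelled under fitted GTR+I+G models."""
    return make_corpus(CORPUS_N_DATASETS, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def corpus_jc(corpus_gtr):
    """The same datasets relabelled under Jukes-Cantor.

    Reuses the already-simulated alignments and true trees so only the
    labelling pipeline is rerun.
    """
    from sprank.simulate import Corpus, label_dataset

    datasets = [
        label_dataset(ds.dataset_id, ds.alignment, ds.true_tree, label_model="jc")
        for ds in corpus_gtr.datasets
    ]
    manifest = dict(corpus_gtr.manifest, label_model="jc")
    return Corpus(datasets=datasets, manifest=manifest)


@pytest.fixture(scope="session")
def rank_model(corpus_gtr):
    """A forest ranker trained on the full GTR corpus (used by the search
    tests on freshly simulated datasets, so there is no leakage)."""
    from sprank.features import FEATURE_NAMES
    from sprank.learner import train

    frame = corpus_gtr.to_frame()
    return train(
        frame[list(FEATURE_NAMES)].to_numpy(),
        frame["transformed_target"].to_numpy(),
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
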