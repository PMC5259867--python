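import numpy as np
import pytest

from dtiens.data import EntityFeatureTable, InteractionSet, PairFeaturizer
from dtiens import synthgen


@pytest.fixture
def tiny_drugs() -> EntityFeatureTable:
    rng = np.random.default_rng(11)
    return EntityFeatureTable(
        [f"D{i}" for i in range(6)],
        ["logp", "mw", "tpsa"],
        rng.uniform(size=(6, 3)),
    )


@pytest.fixture
def tiny_targets() -> EntityFeatureTable:
    rng = np.random.default_rng(12)
    return EntityFeatureTable(
        [f"T{i}" for i in range(5)],
        ["aac", "dipep"],
        rng.uniform(size=(5, 2)),
    )


@pytest.fixture
def tiny_interactions(tiny_drugs, tiny_targets) -> InteractionSet:
    pairs = [("D0", "T0"), ("D1", "T1"), ("D2", "T2"), ("D3", "T0"),
             ("D4", "T3")]
    return InteractionSet(pairs, list(tiny_drugs.ids), list(tiny_targets.ids))


@pytest.fixture
def tiny_featurizer(tiny_drugs, tiny_targets) -> PairFeaturizer:
    return PairFeaturizer(tiny_drugs, tiny_targets)


@pytest.fixture(scope="session")
def clean_synth():
    """Noiseless planted dataset: the concept rule is exactly learnable."""
    cfg = synthgen.SynthConfig(n_drugs=80, n_targets=80, n_positives=200,
                               n_concepts=2, noise_sd=0.0, seed=7)
    return synthgen.generate(cfg)
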