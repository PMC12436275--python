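import numpy as np
import pytest

import paretomol as pm
from paretomol.fixtures import FixtureSpec, make_toy_corpus
from paretomol.generator import GeneratorConfig, SmilesGenerator


@pytest.fixture(scope="session")
def toy_corpus() -> list[str]:
    return make_toy_corpus(FixtureSpec(n=1000, seed=2))


@pytest.fixture(scope="session")
def vocab(toy_corpus):
    return pm.build_vocabulary(pm.tokenize(s) for s in toy_corpus)


@pytest.fixture(scope="session")
def tiny_config(vocab) -> GeneratorConfig:
    """Smallest generator that still exercises every architectural piece:
    two blocks (so the inter-block rectifier+projection runs) and
    multi-head attention."""
    return GeneratorConfig(vocab_size=len(vocab), embed_dim=16,
                           hidden_size=32, block_layers=2, num_blocks=2,
                           attention_heads=2, max_len=60, batch_size=32,
                           seed=0)


@pytest.fixture()
def tiny_generator(tiny_config, vocab) -> SmilesGenerator:
    return SmilesGenerator(tiny_config, vocab)


@pytest.fixture(scope="session")
def trained_generator(vocab, toy_corpus) -> SmilesGenerator:
    """A small generator trained enough to produce mostly-valid SMILES;
    shared across tests that need a sensible sampling distribution."""
    cfg = GeneratorConfig(vocab_size=len(vocab), embed_dim=32,
                          hidden_size=64, block_layers=2, num_blocks=1,
                          attention_heads=2, max_len=60, batch_size=32,
                          seed=5)
    model = SmilesGenerator(cfg, vocab)
    model.train_corpus(toy_corpus, epochs=35, seed=5)
    return model
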