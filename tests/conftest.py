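import numpy as np
import pytest

from cropvqa.model import ModelConfig, build_model
from cropvqa.synthetic import BiasSpec, generate_biased_corpus


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small biased corpus shared across tests (seeded, deterministic)."""
    train, val, test, images, specs = generate_biased_corpus(
        40, bias=BiasSpec(bias_strength=0.9), seed=123)
    return {"train": train, "val": val, "test": test,
            "images": images, "specs": specs}


@pytest.fixture(scope="session")
def tiny_model(tiny_corpus):
    """An untrained toy model built on the tiny corpus vocabularies."""
    cfg = ModelConfig(d_model=16, n_heads=2, d_ff=32, n_layers=2, d_emb=8,
                      d_v=16, fusion_ranks=(4, 4, 4), branch_hidden=16,
                      grid=4, resize_to=64, seed=7)
    return build_model(tiny_corpus["train"], cfg)
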