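"""Shared fixtures: the worked-example document, small synthetic corpora,
and a reduced model configuration that keeps unit tests fast."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cid_rpcnn import (
    ModelConfig,
    SynthConfig,
    corpus_tokens,
    encode_instances,
    generate_candidates,
    generate_corpus,
    generate_worked_example,
    random_embeddings,
)
from cid_rpcnn.model import RPCNNParams
from cid_rpcnn.train import knowledge_bits


@pytest.fixture(scope="session")
def worked_doc():
    return generate_worked_example()


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small deterministic corpus with its knowledge tables."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_corpus(SynthConfig(n_docs=15, seed=3))


def small_config(**overrides) -> ModelConfig:
    """A shrunken model for unit tests (full-size defaults are exercised in
    the shape-contract and end-to-end tests)."""
    base = dict(
        d_w=8,
        d_pc=3,
        d_pa=3,
        filter_sizes=(2, 3),
        filters_per_size=6,
        hidden=5,
        dropout=0.0,
        knowledge_dense=4,
        seed=0,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def tiny_setup(tiny_corpus):
    """Encoded candidates + params + knowledge bits for the tiny corpus."""
    docs, tables = tiny_corpus
    cands = [c for d in docs for c in generate_candidates(d)]
    cfg = small_config()
    vocab = random_embeddings(corpus_tokens(cands), cfg.d_w, seed=0)
    encode_instances(cands, vocab)
    l = cands[0].encoded[0].length
    kbits, layout = knowledge_bits(cands, tables)
    params = RPCNNParams(
        cfg, len(vocab), 2 * l, kb_dim=layout.width, word_vectors=vocab.vectors
    )
    return {
        "docs": docs,
        "tables": tables,
        "cands": cands,
        "cfg": cfg,
        "vocab": vocab,
        "params": params,
        "kbits": kbits,
        "layout": layout,
        "l": l,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
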