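import numpy as np
import pytest

from m6adeg.nn import ModelConfig, TransformerEncoder
from m6adeg.tokenizer import TokenizerConfig, build_vocab, encode
from m6adeg.training import FinetuneConfig, finetune

DNA = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA[rng.integers(4, size=length)])


@pytest.fixture(scope="session")
def tok_cfg3() -> TokenizerConfig:
    return TokenizerConfig(K=3, max_tokens=501)


@pytest.fixture(scope="session")
def vocab3(tok_cfg3):
    return build_vocab(tok_cfg3)


@pytest.fixture(scope="session")
def tiny_trained():
    """A small classifier trained on a separable motif-presence task.

    Sequences of 55 nt; half carry the 6-mer GGTAGG near position 20 and are
    labeled 1.  Used by attribution tests that need a model with real signal.
    Returns (model, vocab, tok_cfg, encoded_positives, encoded_negatives).
    """
    rng = np.random.default_rng(42)
    cfg = TokenizerConfig(K=3, max_tokens=61)
    vocab = build_vocab(cfg)
    motif = "GGTAGG"

    def make(n, planted):
        out = []
        for _ in range(n):
            s = list(random_dna(rng, 55))
            if planted:
                start = int(rng.integers(17, 24))
                s[start : start + len(motif)] = motif
            out.append(encode("".join(s), vocab, cfg))
        return out

    pos, neg = make(60, True), make(60, False)
    mc = ModelConfig(
        n_layers=2, hidden=32, n_heads=2, K=3, max_tokens=61,
        vocab_size=len(vocab), dropout=0.0,
    )
    model = TransformerEncoder(mc, seed=7)
    train = [(t, 1) for t in pos[:48]] + [(t, 0) for t in neg[:48]]
    val = [(t, 1) for t in pos[48:]] + [(t, 0) for t in neg[48:]]
    res = finetune(
        train, val, model,
        FinetuneConfig(learning_rate=3e-4, epochs=6, batch_size=16, seed=7),
        vocab,
    )
    return res.model, vocab, cfg, pos, neg
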