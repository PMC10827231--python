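"""Masked-language-model pre-training and classification fine-tuning.

Pre-training follows the two-phase schedule: mask 15% of real tokens and
train until convergence (or a step cap), then raise the masking rate to 20%
for a further fixed number of steps, holding out 10% of the corpus for
validation throughout.  Because adjacent k-mers overlap, masking a single
token would leak the hidden nucleotide through its neighbours, so each
selection masks a span of K contiguous tokens (the DNABERT-style remedy).

Fine-tuning trains a binary head on the [CLS] representation and keeps the
checkpoint with the best validation AUC (earliest epoch on ties).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from m6adeg.metrics import roc_auc
from m6adeg.nn import AdamW, ModelConfig, TransformerEncoder
from m6adeg.tokenizer import KmerVocabulary, TokenizedSequence, TokenizerConfig, encode

logger = logging.getLogger(__name__)

IGNORE_INDEX = -100


@dataclass(frozen=True)
class PretrainSchedule:
    """Two-phase MLM schedule (desk-scale step defaults)."""

    phase1_mask_rate: float = 0.15
    phase1_max_steps: int = 300
    phase2_mask_rate: float = 0.20
    phase2_steps: int = 100
    holdout_fraction: float = 0.10
    batch_size: int = 16
    lr: float = 3e-4
    warmup_steps: int = 30
    eval_every: int = 50
    convergence_tol: float = 1e-3
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.phase1_mask_rate, self.phase2_mask_rate):
            if not 0 < r < 1:
                raise ValueError(f"mask rate must be in (0,1), got {r}")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0,1)")


@dataclass(frozen=True)
class FinetuneConfig:
    """Classification fine-tuning settings (reference defaults: lr 1e-5, 100 epochs)."""

    learning_rate: float = 1e-5
    epochs: int = 100
    batch_size: int = 16
    warmup_steps: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class MaskedBatch:
    """Masked input ids with MLM labels (original ids at masked slots)."""

    input_ids: np.ndarray
    labels: np.ndarray
    mask_positions: tuple[int, ...]


def mask_tokens(
    tok: TokenizedSequence,
    rate: float,
    rng: np.random.Generator,
    vocab: KmerVocabulary,
) -> MaskedBatch:
    """Span-mask ceil(rate * n_kmers) real tokens of one sequence.

    Span centers are drawn uniformly among real-token positions; each
    selection covers K contiguous tokens clipped to the k-mer body, so a
    masked nucleotide is never revealed by an overlapping unmasked k-mer.
    Within the selected set, 80% become [MASK], 10% a random k-mer and 10%
    stay unchanged.  Special tokens are never masked.
    """
    if not 0 < rate < 1:
        raise ValueError(f"rate must be in (0,1), got {rate}")
    n = tok.n_kmers
    if n == 0:
        raise ValueError("sequence has no real tokens to mask")
    K = vocab.K
    target = math.ceil(rate * n)
    body_lo, body_hi = 1, tok.n_kmers  # inclusive token-position bounds
    selected: list[int] = []
    in_sel = set()
    while len(selected) < target:
        c = int(rng.integers(body_lo, body_hi + 1))
        start = max(body_lo, min(c - K // 2, body_hi - K + 1))
        for pos in range(start, min(start + K, body_hi + 1)):
            if pos not in in_sel:
                in_sel.add(pos)
                selected.append(pos)
    selected = selected[:target]  # trim the last span's overshoot
    ids = np.array(tok.ids, dtype=np.int64)
    labels = np.full(len(ids), IGNORE_INDEX, dtype=np.int64)
    n_kmer_vocab = len(vocab) - len(vocab.special_ids)
    for pos in selected:
        labels[pos] = ids[pos]
        u = rng.random()
        if u < 0.8:
            ids[pos] = vocab.mask_id
        elif u < 0.9:
            ids[pos] = vocab.first_kmer_id + int(rng.integers(n_kmer_vocab))
        # else: unchanged
    return MaskedBatch(input_ids=ids, labels=labels, mask_positions=tuple(sorted(selected)))


def encode_corpus(
    seqs: list[str], vocab: KmerVocabulary, config: TokenizerConfig
) -> list[TokenizedSequence]:
    return [encode(s, vocab, config) for s in seqs]


@dataclass
class PretrainResult:
    model: TransformerEncoder
    trace: list[dict] = field(default_factory=list)  # step, phase, split, loss, acc


def pretrain(
    corpus: list[TokenizedSequence],
    model_config: ModelConfig,
    sched: PretrainSchedule,
    vocab: KmerVocabulary,
    model: TransformerEncoder | None = None,
) -> PretrainResult:
    """Two-phase MLM pre-training over a tokenized corpus, fully seeded."""
    if not corpus:
        raise ValueError("empty pre-training corpus")
    rng = np.random.default_rng(sched.seed)
    if model is None:
        model = TransformerEncoder(model_config, seed=sched.seed)
    pad_id = vocab.pad_id
    idx = rng.permutation(len(corpus))
    n_hold = max(1, int(round(sched.holdout_fraction * len(corpus))))
    hold_idx, train_idx = idx[:n_hold], idx[n_hold:]
    if len(train_idx) == 0:
        train_idx = hold_idx
    opt = AdamW(lr=sched.lr, warmup_steps=sched.warmup_steps)
    trace: list[dict] = []

    def masked_arrays(indices, rate):
        batches = [mask_tokens(corpus[i], rate, rng, vocab) for i in indices]
        return (
            np.stack([b.input_ids for b in batches]),
            np.stack([b.labels for b in batches]),
        )

    def evaluate(rate, step, phase):
        sub = hold_idx[: min(64, len(hold_idx))]
        ids, labels = masked_arrays(sub, rate)
        loss, acc = model.mlm_eval_loss(ids, labels, pad_id)
        trace.append({"step": step, "phase": phase, "split": "holdout", "loss": loss, "acc": acc})
        return loss

    step = 0
    for phase, rate, max_steps in (
        (1, sched.phase1_mask_rate, sched.phase1_max_steps),
        (2, sched.phase2_mask_rate, sched.phase2_steps),
    ):
        best = math.inf
        stalls = 0
        phase_step = 0
        while phase_step < max_steps:
            batch_idx = rng.choice(train_idx, size=min(sched.batch_size, len(train_idx)), replace=False)
            ids, labels = masked_arrays(batch_idx, rate)
            loss, acc, grads = model.mlm_loss_and_grads(ids, labels, pad_id)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"MLM loss diverged (non-finite) at step {step}; lower the learning rate"
                )
            opt.step(model.params, grads)
            step += 1
            phase_step += 1
            trace.append({"step": step, "phase": phase, "split": "train", "loss": loss, "acc": acc})
            if step % sched.eval_every == 0:
                hold_loss = evaluate(rate, step, phase)
                if phase == 1:
                    if hold_loss > best - sched.convergence_tol:
                        stalls += 1
                        if stalls >= sched.patience:
                            logger.info("phase 1 converged at step %d", step)
                            break
                    else:
                        stalls = 0
                    best = min(best, hold_loss)
        evaluate(rate, step, phase)
    return PretrainResult(model=model, trace=trace)


@dataclass
class FinetuneResult:
    model: TransformerEncoder  # best checkpoint restored
    best_epoch: int
    best_auc: float
    trace: list[dict] = field(default_factory=list)  # epoch, train_loss, val_auc


def finetune(
    train: list[tuple[TokenizedSequence, int]],
    val: list[tuple[TokenizedSequence, int]],
    model: TransformerEncoder,
    cfg: FinetuneConfig,
    vocab: KmerVocabulary,
) -> FinetuneResult:
    """Train the binary head (and full encoder), select the best-val-AUC epoch."""
    for name, part in (("train", train), ("validation", val)):
        labels = {y for _, y in part}
        if labels != {0, 1}:
            raise ValueError(f"{name} set must contain both classes, has labels {labels}")
    rng = np.random.default_rng(cfg.seed)
    pad_id = vocab.pad_id
    X = np.stack([np.array(t.ids, dtype=np.int64) for t, _ in train])
    y = np.array([lbl for _, lbl in train], dtype=np.float64)
    Xv = np.stack([np.array(t.ids, dtype=np.int64) for t, _ in val])
    yv = np.array([lbl for _, lbl in val], dtype=np.int64)
    opt = AdamW(lr=cfg.learning_rate, warmup_steps=cfg.warmup_steps)
    trace: list[dict] = []
    best_auc, best_epoch, best_state = -np.inf, -1, None
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(X))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            loss, _, grads = model.cls_loss_and_grads(X[sel], y[sel], pad_id, dropout_rng=rng)
            if not np.isfinite(loss):
                raise FloatingPointError(f"classification loss diverged at epoch {epoch}")
            opt.step(model.params, grads)
            losses.append(loss)
        val_scores = predict_ids(model, Xv, pad_id)
        val_auc = roc_auc(val_scores, yv)
        trace.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auc": val_auc})
        if val_auc > best_auc:  # strict: earliest epoch wins ties
            best_auc, best_epoch = val_auc, epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return FinetuneResult(model=model, best_epoch=best_epoch, best_auc=best_auc, trace=trace)


def predict_ids(model: TransformerEncoder, ids: np.ndarray, pad_id: int, batch_size: int = 32) -> np.ndarray:
    out = [
        model.predict_proba(ids[lo : lo + batch_size], pad_id)
        for lo in range(0, len(ids), batch_size)
    ]
    return np.concatenate(out)


def predict(
    seqs: list[str],
    model: TransformerEncoder,
    vocab: KmerVocabulary,
    config: TokenizerConfig,
) -> np.ndarray:
    """Eval-mode probability that each sequence regulates mRNA degradation."""
    toks = encode_corpus(seqs, vocab, config)
    ids = np.stack([np.array(t.ids, dtype=np.int64) for t in toks])
    return predict_ids(model, ids, vocab.pad_id)


def save_checkpoint(path, model: TransformerEncoder, vocab: KmerVocabulary) -> None:
    """Weights + architecture + a vocabulary hash, as a .npz file."""
    import hashlib

    c = model.config
    vhash = hashlib.sha256(
        "".join(f"{t}:{i}" for t, i in sorted(vocab.token_to_id.items())).encode()
    ).hexdigest()
    meta = np.array(
        [c.n_layers, c.hidden, c.n_heads, c.K, c.max_tokens, c.vocab_size, c.ffn_mult],
        dtype=np.int64,
    )
    np.savez(
        path,
        __meta__=meta,
        __dropout__=np.array([c.dropout]),
        __vocab_hash__=np.array([vhash]),
        **model.params,
    )


def load_checkpoint(path, vocab: KmerVocabulary | None = None) -> TransformerEncoder:
    import hashlib

    data = np.load(path, allow_pickle=False)
    meta = data["__meta__"]
    cfg = ModelConfig(
        n_layers=int(meta[0]), hidden=int(meta[1]), n_heads=int(meta[2]),
        K=int(meta[3]), max_tokens=int(meta[4]), vocab_size=int(meta[5]),
        ffn_mult=int(meta[6]), dropout=float(data["__dropout__"][0]),
    )
    if vocab is not None:
        vhash = hashlib.sha256(
            "".join(f"{t}:{i}" for t, i in sorted(vocab.token_to_id.items())).encode()
        ).hexdigest()
        if vhash != str(data["__vocab_hash__"][0]):
            raise ValueError("checkpoint vocabulary hash does not match the supplied vocabulary")
    model = TransformerEncoder(cfg, seed=0)
    model.load_state_dict({k: data[k] for k in model.params})
    return model
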