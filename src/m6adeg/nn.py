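"""A small BERT-style transformer encoder in pure NumPy.

Forward and backward passes are written by hand so that the package is
self-contained on CPU and so that gradients with respect to the embedding
layer — required by integrated-gradients attribution — are available exactly.

Architecture: token + learned position embeddings, N pre-norm transformer
blocks (multi-head self-attention, GELU feed-forward), a final layer norm,
an MLM head (linear to vocabulary) and a binary classification head (dropout
+ single linear layer on the [CLS] vector, sigmoid output).

Pre-norm (LayerNorm before each sub-layer) is used instead of the original
post-norm because it trains stably without a long warmup at the small model
sizes this package typically runs; the full-scale 12x768x12 configuration
instantiates and runs forward identically.

All randomness flows through explicitly passed ``numpy.random.Generator``
objects; runs with equal seeds are bit-identical on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = ["ModelConfig", "TransformerEncoder", "AdamW"]

_NEG_INF = -1e9
_LN_EPS = 1e-5
_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class ModelConfig:
    """Transformer hyperparameters.

    The published configuration is 12 layers, 768 hidden units, 12 heads;
    desk-scale defaults are far smaller and set by the caller.
    """

    n_layers: int = 12
    hidden: int = 768
    n_heads: int = 12
    K: int = 3
    max_tokens: int = 501
    vocab_size: int = 4**3 + 5
    ffn_mult: int = 4
    dropout: float = 0.1  # classification-head dropout

    def __post_init__(self) -> None:
        if self.hidden % self.n_heads != 0:
            raise ValueError(f"hidden {self.hidden} not divisible by n_heads {self.n_heads}")
        for name in ("n_layers", "hidden", "n_heads", "K", "max_tokens", "vocab_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x * _INV_SQRT2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x * _INV_SQRT2)) + x * np.exp(-0.5 * x * x) * _INV_SQRT2PI


def _softmax_lastaxis(x: np.ndarray) -> np.ndarray:
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


def _ln_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xn = xc * inv
    return g * xn + b, (xn, inv, g)


def _ln_bwd(dout, cache):
    xn, inv, g = cache
    H = xn.shape[-1]
    dg = (dout * xn).reshape(-1, H).sum(axis=0)
    db = dout.reshape(-1, H).sum(axis=0)
    dxn = dout * g
    dx = (inv / H) * (
        H * dxn
        - dxn.sum(axis=-1, keepdims=True)
        - xn * (dxn * xn).sum(axis=-1, keepdims=True)
    )
    return dx, dg, db


def _lin_fwd(x, W, b):
    return x @ W + b, (x, W)


def _lin_bwd(dout, cache):
    x, W = cache
    dx = dout @ W.T
    dW = x.reshape(-1, x.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
    db = dout.reshape(-1, dout.shape[-1]).sum(axis=0)
    return dx, dW, db


class TransformerEncoder:
    """Parameters plus forward/backward passes for the encoder and its heads."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        c = config
        init = lambda *shape: (rng.standard_normal(shape) * 0.02).astype(self.dtype)
        zeros = lambda *shape: np.zeros(shape, dtype=self.dtype)
        ones = lambda *shape: np.ones(shape, dtype=self.dtype)
        p: dict[str, np.ndarray] = {
            "tok_emb": init(c.vocab_size, c.hidden),
            "pos_emb": init(c.max_tokens, c.hidden),
            "lnf_g": ones(c.hidden),
            "lnf_b": zeros(c.hidden),
            "mlm_W": init(c.hidden, c.vocab_size),
            "mlm_b": zeros(c.vocab_size),
            "cls_w": init(c.hidden, 1),
            "cls_b": zeros(1),
        }
        for l in range(c.n_layers):
            f = c.ffn_mult * c.hidden
            p.update({
                f"l{l}.ln1_g": ones(c.hidden), f"l{l}.ln1_b": zeros(c.hidden),
                f"l{l}.Wq": init(c.hidden, c.hidden), f"l{l}.bq": zeros(c.hidden),
                f"l{l}.Wk": init(c.hidden, c.hidden), f"l{l}.bk": zeros(c.hidden),
                f"l{l}.Wv": init(c.hidden, c.hidden), f"l{l}.bv": zeros(c.hidden),
                f"l{l}.Wo": init(c.hidden, c.hidden), f"l{l}.bo": zeros(c.hidden),
                f"l{l}.ln2_g": ones(c.hidden), f"l{l}.ln2_b": zeros(c.hidden),
                f"l{l}.W1": init(c.hidden, f), f"l{l}.b1": zeros(f),
                f"l{l}.W2": init(f, c.hidden), f"l{l}.b2": zeros(c.hidden),
            })
        self.params = p

    # ------------------------------------------------------------------ util
    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].astype(self.dtype).copy()

    def attention_bias(self, ids: np.ndarray, pad_id: int) -> np.ndarray:
        """(B,1,1,T) additive bias: -inf at [PAD] key positions."""
        pad = ids == pad_id
        bias = np.zeros(ids.shape, dtype=self.dtype)
        bias[pad] = _NEG_INF
        return bias[:, None, None, :]

    def embed(self, ids: np.ndarray) -> np.ndarray:
        """Token + position embeddings; ids is (B,T)."""
        T = ids.shape[1]
        return self.params["tok_emb"][ids] + self.params["pos_emb"][:T]

    # --------------------------------------------------------------- encoder
    def encoder_forward(self, h0: np.ndarray, bias: np.ndarray):
        """Run the block stack + final LN from embedding input h0 (B,T,H)."""
        p, c = self.params, self.config
        nh, dh = c.n_heads, c.hidden // c.n_heads
        scale = 1.0 / np.sqrt(dh)
        B, T, H = h0.shape
        h = h0
        caches = []
        for l in range(c.n_layers):
            a, ln1c = _ln_fwd(h, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            q, qc = _lin_fwd(a, p[f"l{l}.Wq"], p[f"l{l}.bq"])
            k, kc = _lin_fwd(a, p[f"l{l}.Wk"], p[f"l{l}.bk"])
            v, vc = _lin_fwd(a, p[f"l{l}.Wv"], p[f"l{l}.bv"])
            qh = q.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            S = np.matmul(qh, kh.transpose(0, 1, 3, 2)) * scale + bias
            A = _softmax_lastaxis(S)
            ctx = np.matmul(A, vh)  # (B,nh,T,dh)
            ctx2 = ctx.transpose(0, 2, 1, 3).reshape(B, T, H)
            o, oc = _lin_fwd(ctx2, p[f"l{l}.Wo"], p[f"l{l}.bo"])
            h = h + o
            f_in, ln2c = _ln_fwd(h, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
            u, w1c = _lin_fwd(f_in, p[f"l{l}.W1"], p[f"l{l}.b1"])
            g = _gelu(u)
            ff, w2c = _lin_fwd(g, p[f"l{l}.W2"], p[f"l{l}.b2"])
            h = h + ff
            caches.append((ln1c, qc, kc, vc, qh, kh, vh, A, oc, ln2c, w1c, u, w2c))
        out, lnfc = _ln_fwd(h, p["lnf_g"], p["lnf_b"])
        return out, (caches, lnfc, h0.shape)

    def encoder_backward(self, dout: np.ndarray, cache, grads: dict[str, np.ndarray]):
        """Backprop through the stack; returns d(loss)/d(h0)."""
        p, c = self.params, self.config
        nh, dh = c.n_heads, c.hidden // c.n_heads
        scale = 1.0 / np.sqrt(dh)
        caches, lnfc, (B, T, H) = cache
        dh_, dg, db = _ln_bwd(dout, lnfc)
        grads["lnf_g"] += dg
        grads["lnf_b"] += db
        for l in reversed(range(c.n_layers)):
            ln1c, qc, kc, vc, qh, kh, vh, A, oc, ln2c, w1c, u, w2c = caches[l]
            # FFN branch
            dff = dh_
            dg_, dW2, db2 = _lin_bwd(dff, w2c)
            grads[f"l{l}.W2"] += dW2
            grads[f"l{l}.b2"] += db2
            du = dg_ * _gelu_grad(u)
            df_in, dW1, db1 = _lin_bwd(du, w1c)
            grads[f"l{l}.W1"] += dW1
            grads[f"l{l}.b1"] += db1
            dx_ln2, dg2, db2_ = _ln_bwd(df_in, ln2c)
            grads[f"l{l}.ln2_g"] += dg2
            grads[f"l{l}.ln2_b"] += db2_
            dh_ = dh_ + dx_ln2
            # attention branch
            do = dh_
            dctx2, dWo, dbo = _lin_bwd(do, oc)
            grads[f"l{l}.Wo"] += dWo
            grads[f"l{l}.bo"] += dbo
            dctx = dctx2.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
            dA = np.matmul(dctx, vh.transpose(0, 1, 3, 2))
            dvh = np.matmul(A.transpose(0, 1, 3, 2), dctx)
            dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
            dqh = np.matmul(dS, kh) * scale
            dkh = np.matmul(dS.transpose(0, 1, 3, 2), qh) * scale
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, H)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, H)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, H)
            da = np.zeros_like(dq)
            for d_, cch, nW, nb in ((dq, qc, "Wq", "bq"), (dk, kc, "Wk", "bk"), (dv, vc, "Wv", "bv")):
                dx_, dW_, db_ = _lin_bwd(d_, cch)
                da += dx_
                grads[f"l{l}.{nW}"] += dW_
                grads[f"l{l}.{nb}"] += db_
            dx_ln1, dg1, db1_ = _ln_bwd(da, ln1c)
            grads[f"l{l}.ln1_g"] += dg1
            grads[f"l{l}.ln1_b"] += db1_
            dh_ = dh_ + dx_ln1
        return dh_

    # ----------------------------------------------------------------- heads
    def mlm_loss_and_grads(self, ids: np.ndarray, labels: np.ndarray, pad_id: int):
        """Mean masked cross-entropy and parameter grads.

        ``labels`` holds original token ids at masked positions and -100
        elsewhere; only masked positions contribute to the loss.
        """
        p = self.params
        bias = self.attention_bias(ids, pad_id)
        h0 = self.embed(ids)
        hL, cache = self.encoder_forward(h0, bias)
        mpos = labels != -100
        n_masked = int(mpos.sum())
        if n_masked == 0:
            raise ValueError("batch has no masked positions")
        hm = hL[mpos]  # (M,H)
        logits = hm @ p["mlm_W"] + p["mlm_b"]
        probs = _softmax_lastaxis(logits)
        tgt = labels[mpos]
        ll = -np.log(np.maximum(probs[np.arange(n_masked), tgt], 1e-30))
        loss = float(ll.mean())
        acc = float((logits.argmax(axis=-1) == tgt).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n_masked), tgt] -= 1.0
        dlogits /= n_masked
        grads = self.zero_grads()
        grads["mlm_W"] += hm.T @ dlogits
        grads["mlm_b"] += dlogits.sum(axis=0)
        dhL = np.zeros_like(hL)
        dhL[mpos] = dlogits @ p["mlm_W"].T
        dh0 = self.encoder_backward(dhL, cache, grads)
        self._embedding_backward(ids, dh0, grads)
        return loss, acc, grads

    def mlm_eval_loss(self, ids: np.ndarray, labels: np.ndarray, pad_id: int):
        p = self.params
        hL, _ = self.encoder_forward(self.embed(ids), self.attention_bias(ids, pad_id))
        mpos = labels != -100
        hm = hL[mpos]
        logits = hm @ p["mlm_W"] + p["mlm_b"]
        probs = _softmax_lastaxis(logits)
        tgt = labels[mpos]
        ll = -np.log(np.maximum(probs[np.arange(len(tgt)), tgt], 1e-30))
        acc = float((logits.argmax(axis=-1) == tgt).mean())
        return float(ll.mean()), acc

    def _embedding_backward(self, ids, dh0, grads) -> None:
        np.add.at(grads["tok_emb"], ids.reshape(-1), dh0.reshape(-1, dh0.shape[-1]))
        grads["pos_emb"][: ids.shape[1]] += dh0.sum(axis=0)

    def cls_logit_from_embeddings(self, h0: np.ndarray, bias: np.ndarray):
        """Positive-class logit from embedding input; used by IG."""
        hL, cache = self.encoder_forward(h0, bias)
        z = hL[:, 0, :] @ self.params["cls_w"][:, 0] + self.params["cls_b"][0]
        return z, (cache, hL)

    def cls_logit_grad_wrt_embeddings(self, h0: np.ndarray, bias: np.ndarray):
        """z and dz/dh0 for each sample (no parameter grads, eval mode)."""
        z, (cache, hL) = self.cls_logit_from_embeddings(h0, bias)
        dhL = np.zeros_like(hL)
        dhL[:, 0, :] = self.params["cls_w"][:, 0]
        grads = self.zero_grads()  # discarded
        dh0 = self.encoder_backward(dhL, cache, grads)
        return z, dh0

    def cls_loss_and_grads(
        self, ids: np.ndarray, y: np.ndarray, pad_id: int,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Binary cross-entropy on the [CLS] vector; dropout if rng given."""
        p, c = self.params, self.config
        bias = self.attention_bias(ids, pad_id)
        h0 = self.embed(ids)
        hL, cache = self.encoder_forward(h0, bias)
        hc = hL[:, 0, :]
        if dropout_rng is not None and c.dropout > 0:
            keep = (dropout_rng.random(hc.shape) >= c.dropout).astype(self.dtype)
            hc_d = hc * keep / (1.0 - c.dropout)
        else:
            keep = None
            hc_d = hc
        y = np.asarray(y, dtype=self.dtype)
        z = hc_d @ p["cls_w"][:, 0] + p["cls_b"][0]
        # numerically stable BCE-with-logits
        loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
        prob = 1.0 / (1.0 + np.exp(-z))
        dz = ((prob - y) / len(y)).astype(self.dtype)
        grads = self.zero_grads()
        grads["cls_w"][:, 0] += hc_d.T @ dz
        grads["cls_b"][0] += dz.sum()
        dhc = np.outer(dz, p["cls_w"][:, 0])
        if keep is not None:
            dhc = dhc * keep / (1.0 - c.dropout)
        dhL = np.zeros_like(hL)
        dhL[:, 0, :] = dhc
        dh0 = self.encoder_backward(dhL, cache, grads)
        self._embedding_backward(ids, dh0, grads)
        return loss, prob, grads

    def predict_proba(self, ids: np.ndarray, pad_id: int) -> np.ndarray:
        """Deterministic eval-mode probability of the positive class."""
        bias = self.attention_bias(ids, pad_id)
        z, _ = self.cls_logit_from_embeddings(self.embed(ids), bias)
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class AdamW:
    """AdamW with linear warmup then constant learning rate.

    Weight decay is applied to matrices only (not biases, layer norms or
    embeddings), decoupled from the gradient step.
    """

    lr: float = 1e-4
    warmup_steps: int = 50
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 0.01
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def _decayable(self, name: str) -> bool:
        return name.endswith(("W", "Wq", "Wk", "Wv", "Wo", "W1", "W2", "mlm_W", "cls_w"))

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * min(1.0, self.t / max(1, self.warmup_steps))
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            upd = mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and self._decayable(k):
                upd = upd + self.weight_decay * params[k]
            params[k] -= (lr_t * upd).astype(params[k].dtype)
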