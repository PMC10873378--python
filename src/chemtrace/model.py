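"""Encoder--decoder Transformer for SMILES translation, on numpy.

The architecture follows the original sequence-to-sequence Transformer:
sinusoidal positional encoding added to scaled token embeddings,
multi-head scaled dot-product attention, position-wise ReLU feed-forward
blocks, residual connections with layer normalization either after each
residual add (post-LN) or before each sublayer (pre-LN), causal masking in
the decoder, and the inverse-square-root warmup learning-rate schedule

    lr(step) = d_model^(-1/2) * min(step^(-1/2), step * warmup^(-3/2)).

Both normalization variants end their encoder and decoder stacks with a
final LayerNorm so that the two variants have identical parameter counts
and differ only in graph placement.

Training uses teacher forcing (the decoder consumes the target shifted
right and predicts it shifted left) with token-level cross-entropy that
excludes padding positions, and gradient accumulation over a configurable
number of sub-batches per optimizer step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .corpus import Batch, Vocabulary

NEG_INF = -1e9


@dataclass
class ModelConfig:
    d_model: int = 512
    d_ff: int = 2048
    n_layers_enc: int = 6
    n_layers_dec: int = 6
    n_heads: int = 8
    dropout: float = 0.1
    activation: str = "relu"
    norm_placement: str = "post_ln"  # or "pre_ln"
    init_scheme: str = "framework_default"  # or "he_normal"
    optimizer: str = "adam"  # or "adamw"
    adamw_weight_decay: float = 0.01
    warmup_steps: int = 4000
    token_budget_per_step: int = 25000
    grad_accum_batches: int = 2
    max_steps: int = 80000
    seed: int = 0

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        for name in ("d_model", "d_ff", "n_layers_enc", "n_layers_dec",
                     "n_heads", "warmup_steps", "token_budget_per_step",
                     "grad_accum_batches", "max_steps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")
        if self.norm_placement not in ("post_ln", "pre_ln"):
            raise ValueError("norm_placement must be post_ln or pre_ln")
        if self.init_scheme not in ("framework_default", "he_normal"):
            raise ValueError("init_scheme must be framework_default or he_normal")
        if self.optimizer not in ("adam", "adamw"):
            raise ValueError("optimizer must be adam or adamw")


def lr_at_step(step: int, cfg: ModelConfig) -> float:
    """Warmup-then-decay schedule of the original Transformer."""
    if step < 1:
        raise ValueError("learning-rate schedule is defined for step >= 1")
    return cfg.d_model ** -0.5 * min(step ** -0.5, step * cfg.warmup_steps ** -1.5)


def sinusoidal_encoding(max_len: int, d_model: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None].astype(np.float64)
    i = np.arange(d_model // 2)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((max_len, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe.astype(np.float32)


@dataclass
class TrainState:
    step: int = 0
    loss_history: list = field(default_factory=list)  # (step, batch loss)


class TransformerSeq2Seq:
    """Translation model over a shared source/target vocabulary."""

    def __init__(self, cfg: ModelConfig, vocab_size: int,
                 src_vocab_size: int | None = None, pad_id: int = 0,
                 max_len: int = 512):
        self.cfg = cfg
        self.vocab_size = vocab_size
        self.src_vocab_size = src_vocab_size or vocab_size
        self.pad_id = pad_id
        self.params: dict[str, Tensor] = {}
        self.no_decay: set[str] = set()
        self.training = True
        self.pe = sinusoidal_encoding(max_len, cfg.d_model)
        self.rng = np.random.default_rng(cfg.seed)  # init then dropout noise
        self._build()

    # ------------------------------------------------------------------ init

    def _param(self, name: str, shape: tuple, kind: str) -> Tensor:
        cfg = self.cfg
        if kind == "bias":
            data = np.zeros(shape, dtype=np.float32)
            self.no_decay.add(name)
        elif kind == "gain":
            data = np.ones(shape, dtype=np.float32)
            self.no_decay.add(name)
        elif kind == "shift":
            data = np.zeros(shape, dtype=np.float32)
            self.no_decay.add(name)
        elif cfg.init_scheme == "he_normal":
            fan_in = shape[0]
            data = self.rng.normal(0.0, math.sqrt(2.0 / fan_in), shape).astype(np.float32)
        elif kind == "embedding":
            data = self.rng.normal(0.0, cfg.d_model ** -0.5, shape).astype(np.float32)
        else:  # Xavier-uniform linear weight
            limit = math.sqrt(6.0 / (shape[0] + shape[1]))
            data = self.rng.uniform(-limit, limit, shape).astype(np.float32)
        t = Tensor(data)
        self.params[name] = t
        return t

    def _build_attention(self, prefix: str):
        d = self.cfg.d_model
        for part in ("q", "k", "v", "o"):
            self._param(f"{prefix}.{part}_w", (d, d), "weight")
            self._param(f"{prefix}.{part}_b", (d,), "bias")

    def _build_ln(self, prefix: str):
        d = self.cfg.d_model
        self._param(f"{prefix}.g", (d,), "gain")
        self._param(f"{prefix}.b", (d,), "shift")

    def _build_ffn(self, prefix: str):
        d, f = self.cfg.d_model, self.cfg.d_ff
        self._param(f"{prefix}.w1", (d, f), "weight")
        self._param(f"{prefix}.b1", (f,), "bias")
        self._param(f"{prefix}.w2", (f, d), "weight")
        self._param(f"{prefix}.b2", (d,), "bias")

    def _build(self):
        cfg = self.cfg
        self._param("src_embed", (self.src_vocab_size, cfg.d_model), "embedding")
        self._param("tgt_embed", (self.vocab_size, cfg.d_model), "embedding")
        for i in range(cfg.n_layers_enc):
            self._build_attention(f"enc.{i}.self")
            self._build_ln(f"enc.{i}.ln1")
            self._build_ffn(f"enc.{i}.ffn")
            self._build_ln(f"enc.{i}.ln2")
        self._build_ln("enc.final_ln")
        for i in range(cfg.n_layers_dec):
            self._build_attention(f"dec.{i}.self")
            self._build_ln(f"dec.{i}.ln1")
            self._build_attention(f"dec.{i}.cross")
            self._build_ln(f"dec.{i}.ln2")
            self._build_ffn(f"dec.{i}.ffn")
            self._build_ln(f"dec.{i}.ln3")
        self._build_ln("dec.final_ln")
        self._param("out_w", (cfg.d_model, self.vocab_size), "weight")
        self._param("out_b", (self.vocab_size,), "bias")

    def num_params(self) -> int:
        return sum(int(t.data.size) for t in self.params.values())

    def train(self, mode: bool = True):
        self.training = mode
        return self

    # --------------------------------------------------------------- forward

    def _dropout(self, x: Tensor) -> Tensor:
        return ad.dropout(x, self.cfg.dropout, self.rng, self.training)

    def _attention(self, prefix: str, x_q: Tensor, x_kv: Tensor,
                   mask_bias: np.ndarray | None) -> Tensor:
        """Multi-head attention. ``mask_bias`` is broadcastable to
        (B, H, Lq, Lk) with NEG_INF at disallowed key positions."""
        p = self.params
        cfg = self.cfg
        h, dh = cfg.n_heads, cfg.d_model // cfg.n_heads
        B, Lq = x_q.shape[0], x_q.shape[1]
        Lk = x_kv.shape[1]

        def heads(t: Tensor, L: int) -> Tensor:
            t = ad.reshape(t, (B, L, h, dh))
            return ad.transpose(t, (0, 2, 1, 3))

        q = heads(ad.linear(x_q, p[f"{prefix}.q_w"], p[f"{prefix}.q_b"]), Lq)
        k = heads(ad.linear(x_kv, p[f"{prefix}.k_w"], p[f"{prefix}.k_b"]), Lk)
        v = heads(ad.linear(x_kv, p[f"{prefix}.v_w"], p[f"{prefix}.v_b"]), Lk)
        scores = ad.scale(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), dh ** -0.5)
        if mask_bias is not None:
            scores = ad.add_const(scores, mask_bias)
        attn = ad.softmax(scores)
        ctx = ad.matmul(attn, v)
        ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (B, Lq, cfg.d_model))
        return ad.linear(ctx, p[f"{prefix}.o_w"], p[f"{prefix}.o_b"])

    def _sublayer(self, x: Tensor, fn, ln_prefix: str) -> Tensor:
        """Residual + norm with the configured placement."""
        p = self.params
        g, b = p[f"{ln_prefix}.g"], p[f"{ln_prefix}.b"]
        if self.cfg.norm_placement == "pre_ln":
            return ad.add(x, self._dropout(fn(ad.layer_norm(x, g, b))))
        return ad.layer_norm(ad.add(x, self._dropout(fn(x))), g, b)

    def _ffn(self, prefix: str, x: Tensor) -> Tensor:
        p = self.params
        hidden = ad.relu(ad.linear(x, p[f"{prefix}.w1"], p[f"{prefix}.b1"]))
        return ad.linear(self._dropout(hidden), p[f"{prefix}.w2"], p[f"{prefix}.b2"])

    def _embed(self, table: str, ids: np.ndarray) -> Tensor:
        x = ad.scale(ad.embedding(self.params[table], ids),
                     math.sqrt(self.cfg.d_model))
        L = ids.shape[1]
        if L > self.pe.shape[0]:
            self.pe = sinusoidal_encoding(2 * L, self.cfg.d_model)
        x = ad.add_const(x, self.pe[None, :L])
        return self._dropout(x)

    @staticmethod
    def _key_pad_bias(ids: np.ndarray, pad_id: int) -> np.ndarray:
        # (B, 1, 1, Lk): block attention into padding keys
        return np.where(ids[:, None, None, :] == pad_id, NEG_INF, 0.0).astype(np.float32)

    def encode(self, src_ids: np.ndarray) -> Tensor:
        src_ids = np.atleast_2d(src_ids)
        bias = self._key_pad_bias(src_ids, self.pad_id)
        x = self._embed("src_embed", src_ids)
        for i in range(self.cfg.n_layers_enc):
            x = self._sublayer(x, lambda t, i=i: self._attention(f"enc.{i}.self", t, t, bias),
                               f"enc.{i}.ln1")
            x = self._sublayer(x, lambda t, i=i: self._ffn(f"enc.{i}.ffn", t),
                               f"enc.{i}.ln2")
        p = self.params
        return ad.layer_norm(x, p["enc.final_ln.g"], p["enc.final_ln.b"])

    def decode(self, tgt_in_ids: np.ndarray, memory: Tensor,
               src_ids: np.ndarray) -> Tensor:
        """Logits (B, Lt, V) for decoder input ``tgt_in_ids``."""
        tgt_in_ids = np.atleast_2d(tgt_in_ids)
        src_ids = np.atleast_2d(src_ids)
        Lt = tgt_in_ids.shape[1]
        causal = np.triu(np.full((Lt, Lt), NEG_INF, dtype=np.float32), k=1)
        self_bias = causal[None, None] + self._key_pad_bias(tgt_in_ids, self.pad_id)
        cross_bias = self._key_pad_bias(src_ids, self.pad_id)
        x = self._embed("tgt_embed", tgt_in_ids)
        for i in range(self.cfg.n_layers_dec):
            x = self._sublayer(x, lambda t, i=i: self._attention(f"dec.{i}.self", t, t, self_bias),
                               f"dec.{i}.ln1")
            x = self._sublayer(x, lambda t, i=i: self._attention(f"dec.{i}.cross", t, memory, cross_bias),
                               f"dec.{i}.ln2")
            x = self._sublayer(x, lambda t, i=i: self._ffn(f"dec.{i}.ffn", t),
                               f"dec.{i}.ln3")
        p = self.params
        x = ad.layer_norm(x, p["dec.final_ln.g"], p["dec.final_ln.b"])
        return ad.linear(x, p["out_w"], p["out_b"])

    def forward(self, src_ids: np.ndarray, tgt_in_ids: np.ndarray) -> Tensor:
        return self.decode(tgt_in_ids, self.encode(src_ids), src_ids)

    # ------------------------------------------------------------- training

    def loss_on_batch(self, batch: Batch) -> Tensor:
        tgt_in = batch.target[:, :-1]
        tgt_out = batch.target[:, 1:]
        logits = self.forward(batch.source, tgt_in)
        V = self.vocab_size
        flat = ad.reshape(logits, (-1, V))
        return ad.cross_entropy_logits(flat, tgt_out.reshape(-1),
                                       tgt_out.reshape(-1) != self.pad_id)

    # ----------------------------------------------------------- inference

    def teacher_forced_predict(self, src_ids: np.ndarray,
                               tgt_ids: np.ndarray) -> np.ndarray:
        """Argmax prediction for every target position given the correct
        preceding target tokens. Returns (B, Lt-1) ids aligned to
        ``tgt_ids[:, 1:]``."""
        was_training = self.training
        self.train(False)
        try:
            with ad.no_grad():
                logits = self.forward(np.atleast_2d(src_ids),
                                      np.atleast_2d(tgt_ids)[:, :-1])
            return logits.data.argmax(axis=-1).astype(np.int32)
        finally:
            self.train(was_training)

    def greedy_decode(self, src_ids: np.ndarray, max_len: int,
                      start_id: int, end_id: int) -> tuple[np.ndarray, np.ndarray]:
        """Greedy decoding from the start token.

        Returns (ids (B, <=max_len) padded after the end token, truncated
        flags for rows that never emitted the end token).
        """
        if max_len < 2:
            raise ValueError("max_len must be >= 2")
        src_ids = np.atleast_2d(src_ids)
        B = src_ids.shape[0]
        was_training = self.training
        self.train(False)
        try:
            with ad.no_grad():
                memory = self.encode(src_ids)
                ys = np.full((B, 1), start_id, dtype=np.int32)
                finished = np.zeros(B, dtype=bool)
                for _ in range(max_len - 1):
                    logits = self.decode(ys, memory, src_ids)
                    nxt = logits.data[:, -1].argmax(axis=-1).astype(np.int32)
                    nxt[finished] = self.pad_id
                    ys = np.concatenate([ys, nxt[:, None]], axis=1)
                    finished |= nxt == end_id
                    if finished.all():
                        break
            return ys, ~finished
        finally:
            self.train(was_training)

    # --------------------------------------------------------- persistence

    def save(self, prefix) -> None:
        """Write ``<prefix>.json`` (config) and ``<prefix>.npz`` (weights)."""
        meta = {"cfg": asdict(self.cfg), "vocab_size": self.vocab_size,
                "src_vocab_size": self.src_vocab_size, "pad_id": self.pad_id}
        with open(f"{prefix}.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)
        np.savez(f"{prefix}.npz", **{k: t.data for k, t in self.params.items()})

    @classmethod
    def load(cls, prefix) -> "TransformerSeq2Seq":
        with open(f"{prefix}.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        model = cls(ModelConfig(**meta["cfg"]), meta["vocab_size"],
                    meta["src_vocab_size"], meta["pad_id"])
        with np.load(f"{prefix}.npz") as data:
            for k in model.params:
                model.params[k].data = data[k]
        return model


class WarmupOptimizer:
    """Adam / AdamW with the inverse-square-root warmup schedule.

    AdamW applies decoupled weight decay to matrix weights only (never to
    biases or normalization parameters)."""

    def __init__(self, model: TransformerSeq2Seq,
                 beta1: float = 0.9, beta2: float = 0.98, eps: float = 1e-9):
        self.model = model
        self.cfg = model.cfg
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.step_count = 0
        self.m = {k: np.zeros_like(t.data) for k, t in model.params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in model.params.items()}

    def zero_grad(self):
        for t in self.model.params.values():
            t.grad = None

    def step(self):
        self.step_count += 1
        lr = lr_at_step(self.step_count, self.cfg)
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.step_count
        bc2 = 1 - b2 ** self.step_count
        decay = (self.cfg.adamw_weight_decay
                 if self.cfg.optimizer == "adamw" else 0.0)
        for k, t in self.model.params.items():
            if t.grad is None:
                continue
            g = t.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if decay and k not in self.model.no_decay:
                update = update + decay * t.data
            t.data = t.data - lr * update


def train_step(model: TransformerSeq2Seq, optimizer: WarmupOptimizer,
               sub_batches: list[Batch], state: TrainState) -> float:
    """One optimizer step: gradients accumulated over ``sub_batches``
    (the token budget per step is split across them), then a single
    parameter update. Returns the mean sub-batch loss."""
    optimizer.zero_grad()
    losses = []
    for batch in sub_batches:
        loss = ad.scale(model.loss_on_batch(batch), 1.0 / len(sub_batches))
        loss.backward()
        losses.append(float(loss.data) * len(sub_batches))
    mean_loss = float(np.mean(losses))
    if not math.isfinite(mean_loss):
        raise RuntimeError(
            f"non-finite loss {mean_loss} at optimizer step {state.step + 1}; "
            "aborting the run"
        )
    optimizer.step()
    state.step += 1
    state.loss_history.append((state.step, mean_loss))
    return mean_loss


def decode_max_len(vocab: Vocabulary, records) -> int:
    """Maximum target token length in a corpus plus a safety margin."""
    longest = max(len(vocab.encode(r.canonical_smiles)) for r in records)
    return longest + 5
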