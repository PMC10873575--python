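"""The NanoCon feature-fusion network.

Two branches encode each candidate site: a Transformer encoder over the 9
overlapping 5-mer tokens of the 13-base motif (multi-head self-attention +
feed-forward blocks with residual connections and layer normalisation), and
a fully connected network over the 39 per-base signal statistics (13 means,
13 standard deviations, 13 lengths).  The signal vector is concatenated onto
every token-context step and a bidirectional GRU integrates the 9 fused
steps; its final forward and backward hidden states form the fused
representation used both by the contrastive objective and by the linear
classifier head.

Ablation variants mirror the masking experiments: ``mask_means`` /
``mask_stds`` / ``mask_lens`` zero one signal track, ``mask_sequence``
zeroes the sequence branch, ``no_gru`` replaces the Bi-GRU with a fully
connected layer over the flattened concatenation, and ``no_contrast``
disables the contrastive objective during training (the architecture is
unchanged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._autograd import Tensor, concat
from . import tokenizer as tok
from .feature_io import MethylInstance

__all__ = ["ABLATION_FLAGS", "ModelConfig", "NanoConModel", "self_attention",
           "prepare_batch"]

ABLATION_FLAGS = frozenset(
    {"mask_means", "mask_stds", "mask_lens", "mask_sequence",
     "no_gru", "no_contrast"})


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are deliberately small enough to train on one CPU: 64-d token
    embeddings, 2 Transformer layers with 4 heads, a [39 -> 64 -> 64] signal
    encoder, and a Bi-GRU of width 64 giving a 128-d fused representation.
    """

    embed_dim: int = 64
    n_transformer_layers: int = 2
    n_heads: int = 4
    signal_encoder_dims: tuple[int, ...] = (64, 64)
    gru_hidden: int = 64
    gru_dropout: float = 0.2
    ablation_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        dims = (self.embed_dim, self.n_transformer_layers, self.n_heads,
                self.gru_hidden, *self.signal_encoder_dims)
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")
        if not 0.0 <= self.gru_dropout < 1.0:
            raise ValueError("gru_dropout must be in [0, 1)")
        unknown = set(self.ablation_flags) - ABLATION_FLAGS
        if unknown:
            raise ValueError(f"unknown ablation flags: {sorted(unknown)}")
        # allow plain iterables in user code / YAML configs
        object.__setattr__(self, "ablation_flags",
                           frozenset(self.ablation_flags))
        object.__setattr__(self, "signal_encoder_dims",
                           tuple(self.signal_encoder_dims))

    @property
    def repr_dim(self) -> int:
        """Fused representation width (2 x gru_hidden in both variants)."""
        return 2 * self.gru_hidden

    def with_flags(self, *flags: str) -> "ModelConfig":
        cfg = asdict(self)
        cfg["ablation_flags"] = frozenset(self.ablation_flags) | set(flags)
        return ModelConfig(**cfg)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ablation_flags"] = sorted(self.ablation_flags)
        d["signal_encoder_dims"] = list(self.signal_encoder_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["ablation_flags"] = frozenset(d.get("ablation_flags", ()))
        d["signal_encoder_dims"] = tuple(d.get("signal_encoder_dims", (64, 64)))
        return cls(**d)


def self_attention(x, w_q, w_k, w_v, return_weights: bool = False):
    """Scaled dot-product self-attention over a step sequence.

    ``softmax(Q K^T / sqrt(d_k)) V`` with Q = XW_Q, K = XW_K, V = XW_V.
    Accepts Tensors or arrays of shape (..., steps, d_model); the projection
    matrices must share their inner dimension with ``x``'s last axis.
    """
    x, w_q, w_k, w_v = (Tensor._lift(a) for a in (x, w_q, w_k, w_v))
    if x.shape[-1] != w_q.shape[0]:
        raise ValueError(
            f"model dim mismatch: x has {x.shape[-1]}, W_Q expects {w_q.shape[0]}")
    q, k, v = x @ w_q, x @ w_k, x @ w_v
    d_k = q.shape[-1]
    weights = ((q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))).softmax(-1)
    out = weights @ v
    if return_weights:
        return out, weights
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


class NanoConModel:
    """Feature-fusion network with named parameters and explicit freezing.

    Parameters are a flat ``{name: Tensor}`` dict; names are prefixed
    ``encoder.`` or ``classifier.`` so the alternating training phases can
    freeze one module wholesale.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 vocab: dict[str, int] | None = None):
        self.config = config or ModelConfig()
        self.vocab = vocab or tok.build_vocab()
        self.vocab_hash = tok.vocab_hash(self.vocab)
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))

    # -- construction ------------------------------------------------------

    def _add(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        e = cfg.embed_dim
        self._add("encoder.tok_embed",
                  rng.normal(0.0, 0.1, size=(len(self.vocab), e)))
        self._add("encoder.pos_embed",
                  rng.normal(0.0, 0.1, size=(tok.N_TOKENS, e)))
        for layer in range(cfg.n_transformer_layers):
            p = f"encoder.transformer.{layer}"
            for mat in ("w_q", "w_k", "w_v", "w_o"):
                self._add(f"{p}.{mat}", _glorot(rng, e, e))
            self._add(f"{p}.ln1.gamma", np.ones(e))
            self._add(f"{p}.ln1.beta", np.zeros(e))
            self._add(f"{p}.ffn.w1", _glorot(rng, e, 2 * e))
            self._add(f"{p}.ffn.b1", np.zeros(2 * e))
            self._add(f"{p}.ffn.w2", _glorot(rng, 2 * e, e))
            self._add(f"{p}.ffn.b2", np.zeros(e))
            self._add(f"{p}.ln2.gamma", np.ones(e))
            self._add(f"{p}.ln2.beta", np.zeros(e))
        dims = (39, *cfg.signal_encoder_dims)
        for i, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
            self._add(f"encoder.signal.{i}.w", _glorot(rng, d_in, d_out))
            self._add(f"encoder.signal.{i}.b", np.zeros(d_out))
        d_fuse = e + cfg.signal_encoder_dims[-1]
        h = cfg.gru_hidden
        if "no_gru" in cfg.ablation_flags:
            self._add("encoder.fuse_fc.w",
                      _glorot(rng, tok.N_TOKENS * d_fuse, cfg.repr_dim))
            self._add("encoder.fuse_fc.b", np.zeros(cfg.repr_dim))
        else:
            for direction in ("fwd", "bwd"):
                p = f"encoder.gru.{direction}"
                self._add(f"{p}.w", _glorot(rng, d_fuse, 3 * h))
                self._add(f"{p}.u", _glorot(rng, h, 3 * h))
                self._add(f"{p}.b", np.zeros(3 * h))
        r = cfg.repr_dim
        self._add("classifier.0.w", _glorot(rng, r, r // 2))
        self._add("classifier.0.b", np.zeros(r // 2))
        self._add("classifier.1.w", _glorot(rng, r // 2, 2))
        self._add("classifier.1.b", np.zeros(2))

    # -- building blocks ---------------------------------------------------

    def _layer_norm(self, x: Tensor, prefix: str, eps: float = 1e-5) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2).mean(axis=-1, keepdims=True)
        normed = centered / (var + eps).sqrt()
        return normed * self.params[f"{prefix}.gamma"] + self.params[f"{prefix}.beta"]

    def _multi_head_attention(self, x: Tensor, prefix: str) -> Tensor:
        cfg = self.config
        b, n, e = x.shape
        h, d = cfg.n_heads, e // cfg.n_heads

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(b, n, h, d).swapaxes(1, 2)  # (b, h, n, d)

        q = split_heads(x @ self.params[f"{prefix}.w_q"])
        k = split_heads(x @ self.params[f"{prefix}.w_k"])
        v = split_heads(x @ self.params[f"{prefix}.w_v"])
        weights = ((q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))).softmax(-1)
        attended = (weights @ v).swapaxes(1, 2).reshape(b, n, e)
        return attended @ self.params[f"{prefix}.w_o"]

    def encode_sequence(self, token_ids: np.ndarray) -> Tensor:
        """Token ids (batch, 9) -> context sequence (batch, 9, embed_dim).

        Under ``mask_sequence`` the branch contributes an all-zero sequence
        of the same shape.
        """
        token_ids = np.asarray(token_ids)
        b = token_ids.shape[0]
        if token_ids.shape != (b, tok.N_TOKENS):
            raise ValueError(f"expected (batch, {tok.N_TOKENS}) token ids")
        if "mask_sequence" in self.config.ablation_flags:
            return Tensor(np.zeros((b, tok.N_TOKENS, self.config.embed_dim)))
        x = (self.params["encoder.tok_embed"].take_rows(token_ids)
             + self.params["encoder.pos_embed"])
        for layer in range(self.config.n_transformer_layers):
            p = f"encoder.transformer.{layer}"
            x = self._layer_norm(x + self._multi_head_attention(x, p), f"{p}.ln1")
            ffn = ((x @ self.params[f"{p}.ffn.w1"]
                    + self.params[f"{p}.ffn.b1"]).relu()
                   @ self.params[f"{p}.ffn.w2"] + self.params[f"{p}.ffn.b2"])
            x = self._layer_norm(x + ffn, f"{p}.ln2")
        return x

    def encode_signal(self, means: np.ndarray, stds: np.ndarray,
                      lens: np.ndarray) -> Tensor:
        """Signal tracks (batch, 13) each -> signal vector (batch, s_dim)."""
        tracks = []
        for name, arr in (("mask_means", means), ("mask_stds", stds),
                          ("mask_lens", lens)):
            arr = np.asarray(arr, dtype=np.float64)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in signal track for {name}")
            if name in self.config.ablation_flags:
                arr = np.zeros_like(arr)
            tracks.append(arr)
        x = Tensor(np.concatenate(tracks, axis=-1))  # (batch, 39)
        n_layers = len(self.config.signal_encoder_dims)
        for i in range(n_layers):
            x = x @ self.params[f"encoder.signal.{i}.w"] + self.params[f"encoder.signal.{i}.b"]
            if i < n_layers - 1:
                x = x.relu()
        return x.relu()

    def fuse(self, context: Tensor, signal: Tensor,
             dropout_rng: np.random.Generator | None = None) -> Tensor:
        """Concatenate the signal vector onto each step and run the Bi-GRU.

        ``dropout_rng`` enables input dropout on the GRU steps (training
        only); passing None gives the deterministic inference path.  Under
        ``no_gru`` a fully connected layer over the flattened concatenation
        replaces the recurrence.
        """
        b, n, _ = context.shape
        tiled = signal.reshape(b, 1, signal.shape[-1]) * np.ones((1, n, 1))
        x = concat([context, tiled], axis=-1)  # (b, 9, d_fuse)
        p_drop = self.config.gru_dropout
        if dropout_rng is not None and p_drop > 0.0:
            mask = (dropout_rng.random(x.shape) >= p_drop) / (1.0 - p_drop)
            x = x * mask
        if "no_gru" in self.config.ablation_flags:
            flat = x.reshape(b, n * x.shape[-1])
            return (flat @ self.params["encoder.fuse_fc.w"]
                    + self.params["encoder.fuse_fc.b"]).relu()
        fwd = self._gru_direction(x, "fwd", reverse=False)
        bwd = self._gru_direction(x, "bwd", reverse=True)
        return concat([fwd, bwd], axis=-1)

    def _gru_direction(self, x: Tensor, direction: str, reverse: bool) -> Tensor:
        h_dim = self.config.gru_hidden
        b, n, _ = x.shape
        p = f"encoder.gru.{direction}"
        w, u, bias = (self.params[f"{p}.w"], self.params[f"{p}.u"],
                      self.params[f"{p}.b"])
        h = Tensor(np.zeros((b, h_dim)))
        steps = range(n - 1, -1, -1) if reverse else range(n)
        for t in steps:
            gi = x[:, t, :] @ w + bias
            gh = h @ u
            r = (gi[:, :h_dim] + gh[:, :h_dim]).sigmoid()
            z = (gi[:, h_dim:2 * h_dim] + gh[:, h_dim:2 * h_dim]).sigmoid()
            nn = (gi[:, 2 * h_dim:] + r * gh[:, 2 * h_dim:]).tanh()
            h = (1.0 - z) * nn + z * h
        return h

    def classify(self, repr_: Tensor) -> Tensor:
        """Fused representation -> class probabilities (batch, 2)."""
        hidden = (repr_ @ self.params["classifier.0.w"]
                  + self.params["classifier.0.b"]).relu()
        logits = hidden @ self.params["classifier.1.w"] + self.params["classifier.1.b"]
        return logits.softmax(-1)

    # -- end-to-end --------------------------------------------------------

    def forward(self, batch: dict[str, np.ndarray],
                dropout_rng: np.random.Generator | None = None,
                ) -> tuple[Tensor, Tensor]:
        """Full forward pass: batch arrays -> (probs (b, 2), repr (b, r))."""
        context = self.encode_sequence(batch["tokens"])
        signal = self.encode_signal(batch["means"], batch["stds"], batch["lens"])
        repr_ = self.fuse(context, signal, dropout_rng=dropout_rng)
        return self.classify(repr_), repr_

    # -- freezing & persistence -------------------------------------------

    def param_names(self, module: str | None = None) -> list[str]:
        if module is None:
            return list(self.params)
        return [k for k in self.params if k.startswith(module + ".")]

    def snapshot(self, module: str | None = None) -> dict[str, np.ndarray]:
        return {k: self.params[k].data.copy()
                for k in self.param_names(module)}

    def load_snapshot(self, snap: dict[str, np.ndarray]) -> None:
        for k, v in snap.items():
            self.params[k].data = v.copy()

    def save(self, path: str | Path) -> None:
        """Save weights + config + vocabulary hash as one .npz archive."""
        meta = json.dumps({"config": self.config.to_dict(),
                           "vocab_hash": self.vocab_hash})
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        np.savez(path, __meta__=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path,
             vocab: dict[str, int] | None = None) -> "NanoConModel":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            model = cls(ModelConfig.from_dict(meta["config"]), vocab=vocab)
            if model.vocab_hash != meta["vocab_hash"]:
                raise ValueError(
                    "vocabulary mismatch between checkpoint and tokenizer")
            for key in archive.files:
                if key == "__meta__":
                    continue
                model.params[key.replace("__", ".")].data = archive[key]
        return model


def prepare_batch(instances: Sequence[MethylInstance],
                  vocab: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Convert instances to the array batch the model consumes."""
    tokens = np.array([tok.tokenize(i.motif, vocab).token_ids
                       for i in instances], dtype=np.int64)
    return {
        "tokens": tokens,
        "means": np.array([i.means for i in instances]),
        "stds": np.array([i.stds for i in instances]),
        "lens": np.array([i.lens for i in instances], dtype=np.float64),
        "labels": np.array([i.label for i in instances], dtype=np.int64),
    }
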