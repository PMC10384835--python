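"""The patch-transformer fall-detection network.

Architecture: each n x n x C patch (one sliding window of the merged sensor
channels, reshaped to a square grid) is embedded to a D = C^2 dimensional
token, either by two stride-2 convolutions (kernel 3, ReLU) followed by a
learned linear projection, or - with local features disabled - by a direct
flatten-and-project.  A learnable positional table is added, the token
sequence passes through L pre-LN transformer encoder layers with h-head
scaled dot-product self-attention, and a final layer norm, global average
pooling over tokens, and a single linear layer produce the two-class
(fall / no-fall) logits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "ModelConfig",
    "PatchTransformer",
    "self_attention",
    "count_params",
    "estimate_flops",
    "save_checkpoint",
    "load_checkpoint",
]


def conv_output_size(n: int, kernel: int = 3, stride: int = 2, padding: int = 1) -> int:
    return (n + 2 * padding - kernel) // stride + 1


@dataclass
class ModelConfig:
    """Hyperparameters of the patch-transformer.

    ``d_model`` is tied to the merged channel count: D = C^2, the number of
    samples in one patch row times one patch column per channel pair.  The
    per-head width is d_k = d_v = d_model / h, so ``heads`` must divide C^2.
    ``attn_scale`` selects the attention-score normaliser: ``"sqrt"`` divides
    by sqrt(d_k) (the standard transformer convention, the default) and
    ``"linear"`` divides by d_k.
    """

    channels: int
    patch_side: int
    seq_len: int
    heads: int = 3
    layers: int = 6
    conv_kernel: int = 3
    conv_stride: int = 2
    conv_channel_factor: int = 2
    mlp_ratio: int = 4
    num_classes: int = 2
    attn_scale: str = "sqrt"
    local_features: bool = True
    mlp_activation: str = "gelu"
    ln_eps: float = 1e-5
    pos_init_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channels < 1 or self.patch_side < 1 or self.seq_len < 1:
            raise ValueError("channels, patch_side and seq_len must be >= 1")
        if self.layers < 1:
            raise ValueError("need at least one encoder layer")
        if self.d_model % self.heads != 0:
            raise ValueError(
                f"heads ({self.heads}) must divide d_model ({self.d_model})"
            )
        if self.attn_scale not in ("sqrt", "linear"):
            raise ValueError("attn_scale must be 'sqrt' or 'linear'")
        if self.local_features and self.patch_side < 4:
            raise ValueError(
                "patch_side must be >= 4 for two stride-2 convolutions; "
                "disable local_features for smaller patches"
            )

    @property
    def d_model(self) -> int:
        return self.channels**2

    @property
    def d_k(self) -> int:
        return self.d_model // self.heads

    @property
    def mlp_hidden(self) -> int:
        return self.mlp_ratio * self.d_model

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# layers


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        sd = np.sqrt(2.0 / (d_in + d_out))
        self.weight = Tensor(rng.normal(0.0, sd, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def named_parameters(self, prefix: str):
        yield f"{prefix}.weight", self.weight
        yield f"{prefix}.bias", self.bias


class Conv2d:
    """kernel x kernel stride-s convolution on (B, H, W, C) via im2col gather."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator):
        fan_in = kernel * kernel * c_in
        sd = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, sd, (fan_in, c_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        self._index_cache: dict[int, tuple[np.ndarray, int]] = {}

    def _indices(self, n: int) -> tuple[np.ndarray, int]:
        if n not in self._index_cache:
            k, s, p = self.kernel, self.stride, self.padding
            np_side = n + 2 * p
            out = conv_output_size(n, k, s, p)
            starts = np.arange(out) * s
            rows = (starts[:, None] + np.arange(k)[None, :])  # (out, k)
            # flat indices into the padded H*W plane for every output position
            idx = (
                rows[:, None, :, None] * np_side  # oh, -, kh, -
                + rows[None, :, None, :]          # -, ow, -, kw
            ).reshape(out * out, k * k)
            self._index_cache[n] = (idx, out)
        return self._index_cache[n]

    def __call__(self, x: Tensor) -> Tensor:
        b, n = x.shape[0], x.shape[1]
        idx, out = self._indices(n)
        xp = x.pad2d(self.padding)
        flat = xp.reshape(b, (n + 2 * self.padding) ** 2, self.c_in)
        patches = flat.gather_rows(idx)  # (B, out*out, k*k, C)
        patches = patches.reshape(b, out * out, self.kernel**2 * self.c_in)
        y = patches @ self.weight + self.bias
        return y.reshape(b, out, out, self.c_out)

    def named_parameters(self, prefix: str):
        yield f"{prefix}.weight", self.weight
        yield f"{prefix}.bias", self.bias


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layernorm(self.eps) * self.gamma + self.beta

    def named_parameters(self, prefix: str):
        yield f"{prefix}.gamma", self.gamma
        yield f"{prefix}.beta", self.beta


def self_attention(x: Tensor, w_q: Tensor, w_k: Tensor, w_v: Tensor,
                   d_k: int, scale: str = "sqrt") -> Tensor:
    """Scaled dot-product self-attention for one head (or broadcast heads).

    ``x`` is (..., N, d_model); the projections are (d_model, d_k).  Scores
    Q K^T are divided by sqrt(d_k) or d_k according to ``scale``, softmaxed
    row-wise, and applied to V.
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    q, k, v = x @ w_q, x @ w_k, x @ w_v
    denom = np.sqrt(d_k) if scale == "sqrt" else float(d_k)
    scores = (q @ k.swapaxes(-1, -2)) / denom
    return scores.softmax() @ v


class MultiHeadSelfAttention:
    """h parallel attention heads, concatenated and projected by W_O."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d, h, dk = cfg.d_model, cfg.heads, cfg.d_k
        sd = np.sqrt(2.0 / (d + dk))
        self.w_q = Tensor(rng.normal(0.0, sd, (h, d, dk)), requires_grad=True)
        self.w_k = Tensor(rng.normal(0.0, sd, (h, d, dk)), requires_grad=True)
        self.w_v = Tensor(rng.normal(0.0, sd, (h, d, dk)), requires_grad=True)
        self.w_o = Linear(h * dk, d, rng)
        self.cfg = cfg

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        b, n = x.shape[0], x.shape[1]
        xh = x.reshape(b, 1, n, cfg.d_model)  # broadcast over heads
        heads = self_attention(xh, self.w_q, self.w_k, self.w_v,
                               cfg.d_k, cfg.attn_scale)  # (B, h, N, d_k)
        merged = heads.swapaxes(1, 2).reshape(b, n, cfg.heads * cfg.d_k)
        return self.w_o(merged)

    def named_parameters(self, prefix: str):
        yield f"{prefix}.w_q", self.w_q
        yield f"{prefix}.w_k", self.w_k
        yield f"{prefix}.w_v", self.w_v
        yield from self.w_o.named_parameters(f"{prefix}.w_o")


class EncoderLayer:
    """Pre-LN residual sub-layer: x' = MSA(LN(x)) + x; out = MLP(LN(x')) + x'."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.ln1 = LayerNorm(cfg.d_model, cfg.ln_eps)
        self.msa = MultiHeadSelfAttention(cfg, rng)
        self.ln2 = LayerNorm(cfg.d_model, cfg.ln_eps)
        self.fc1 = Linear(cfg.d_model, cfg.mlp_hidden, rng)
        self.fc2 = Linear(cfg.mlp_hidden, cfg.d_model, rng)
        self._act = cfg.mlp_activation

    def _mlp(self, x: Tensor) -> Tensor:
        h = self.fc1(x)
        h = h.gelu() if self._act == "gelu" else h.relu()
        return self.fc2(h)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.msa(self.ln1(x)) + x
        return self._mlp(self.ln2(x)) + x

    def named_parameters(self, prefix: str):
        yield from self.ln1.named_parameters(f"{prefix}.ln1")
        yield from self.msa.named_parameters(f"{prefix}.msa")
        yield from self.ln2.named_parameters(f"{prefix}.ln2")
        yield from self.fc1.named_parameters(f"{prefix}.fc1")
        yield from self.fc2.named_parameters(f"{prefix}.fc2")


class PatchTransformer:
    """The full network; ``forward`` maps patch blocks to class logits."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c, n, d = config.channels, config.patch_side, config.d_model

        if config.local_features:
            c_mid = config.conv_channel_factor * c
            self.conv1 = Conv2d(c, c_mid, config.conv_kernel, config.conv_stride, 1, rng)
            self.conv2 = Conv2d(c_mid, c_mid, config.conv_kernel, config.conv_stride, 1, rng)
            side = conv_output_size(conv_output_size(n))
            self.proj = Linear(side * side * c_mid, d, rng)
        else:
            self.conv1 = self.conv2 = None
            self.proj = Linear(n * n * c, d, rng)

        self.pos = Tensor(rng.normal(0.0, config.pos_init_sd, (config.seq_len, d)),
                          requires_grad=True)
        self.encoder = [EncoderLayer(config, rng) for _ in range(config.layers)]
        self.ln_final = LayerNorm(d, config.ln_eps)
        self.head = Linear(d, config.num_classes, rng)

    # -- stages ---------------------------------------------------------------

    def embed(self, blocks: np.ndarray) -> Tensor:
        """Map (B, N, n, n, C) patch blocks to (B, N, D) tokens."""
        b, n_seq = blocks.shape[0], blocks.shape[1]
        n, c = self.config.patch_side, self.config.channels
        x = Tensor(blocks.reshape(b * n_seq, n, n, c))
        if self.conv1 is not None:
            x = self.conv1(x).relu()
            x = self.conv2(x).relu()
            x = x.reshape(b * n_seq, int(np.prod(x.shape[1:])))
        else:
            x = x.reshape(b * n_seq, n * n * c)
        tokens = self.proj(x)
        return tokens.reshape(b, n_seq, self.config.d_model)

    def feature_map(self, blocks: np.ndarray) -> np.ndarray:
        """The D x N local-feature matrix of one patch sequence."""
        if blocks.ndim == 4:
            blocks = blocks[None]
        tokens = self.embed(blocks)
        return tokens.data[0].T  # (D, N)

    def forward(self, blocks: np.ndarray) -> Tensor:
        """(B, N, n, n, C) or (N, n, n, C) blocks -> (B, num_classes) logits."""
        blocks = np.asarray(blocks, dtype=np.float64)
        if blocks.ndim == 4:
            blocks = blocks[None]
        if blocks.shape[1] != self.config.seq_len:
            raise ValueError(
                f"sequence length {blocks.shape[1]} does not match the "
                f"positional table ({self.config.seq_len})"
            )
        x = self.embed(blocks) + self.pos
        for layer in self.encoder:
            x = layer(x)
        y = self.ln_final(x)
        pooled = y.mean(axis=1)  # GAP over the token axis
        return self.head(pooled)

    def predict_proba(self, blocks: np.ndarray) -> np.ndarray:
        """Class probabilities (softmax of the logits), shape (B, 2)."""
        return self.forward(blocks).softmax().data

    def predict(self, blocks: np.ndarray) -> np.ndarray:
        return self.predict_proba(blocks).argmax(axis=-1)

    __call__ = forward

    # -- parameters -----------------------------------------------------------

    def named_parameters(self):
        if self.conv1 is not None:
            yield from self.conv1.named_parameters("conv1")
            yield from self.conv2.named_parameters("conv2")
        yield from self.proj.named_parameters("proj")
        yield "pos", self.pos
        for i, layer in enumerate(self.encoder):
            yield from layer.named_parameters(f"encoder.{i}")
        yield from self.ln_final.named_parameters("ln_final")
        yield from self.head.named_parameters("head")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float64, copy=True)

    def ablate_local_features(self, enabled: bool) -> "PatchTransformer":
        """A fresh variant with the conv embedder switched on or off."""
        cfg = ModelConfig.from_dict({**self.config.to_dict(), "local_features": enabled})
        return PatchTransformer(cfg)


# ---------------------------------------------------------------------------
# accounting


def count_params(model: PatchTransformer) -> int:
    """Exact learnable-parameter tally by enumerating every weight tensor."""
    return sum(p.data.size for p in model.parameters())


def estimate_flops(model: PatchTransformer) -> int:
    """Multiply-add count of one forward pass on a single patch sequence.

    Counts the matrix products (convolutions, token projection, attention
    projections and score/value matmuls, MLP, classifier head); element-wise
    work (layer norm, softmax, activations, residual adds) is excluded.
    """
    cfg = model.config
    n_seq, n, c, d = cfg.seq_len, cfg.patch_side, cfg.channels, cfg.d_model
    total = 0
    if cfg.local_features:
        c_mid = cfg.conv_channel_factor * c
        s1 = conv_output_size(n)
        s2 = conv_output_size(s1)
        total += n_seq * s1 * s1 * (cfg.conv_kernel**2 * c) * c_mid
        total += n_seq * s2 * s2 * (cfg.conv_kernel**2 * c_mid) * c_mid
        total += n_seq * (s2 * s2 * c_mid) * d
    else:
        total += n_seq * (n * n * c) * d
    per_layer = (
        3 * n_seq * d * d          # Q, K, V projections (h heads of d x d_k)
        + n_seq * n_seq * d        # attention scores, all heads
        + n_seq * n_seq * d        # attention-weighted values
        + n_seq * d * d            # output projection W_O
        + 2 * n_seq * d * cfg.mlp_hidden  # MLP
    )
    total += cfg.layers * per_layer
    total += d * cfg.num_classes
    return total


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, model: PatchTransformer) -> None:
    """Archive the config (JSON) and every named weight tensor."""
    arrays = model.state_dict()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> PatchTransformer:
    with np.load(path) as archive:
        cfg = ModelConfig.from_dict(json.loads(bytes(archive["__config__"]).decode()))
        model = PatchTransformer(cfg)
        model.load_state_dict({k: archive[k] for k in archive.files if k != "__config__"})
    return model
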