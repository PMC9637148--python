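"""Three-level attention architecture for expression prediction.

The model reads multi-resolution histone-mark matrices for a promoter and its
interacting pCREs and predicts gene expression through three stacked
transformer submodules, instantiated independently per input resolution:

* **Embedding transformer** — one self-attention encoder layer over the
  position-encoded promoter bins, summarizing the local histone code
  (``X_input -> X_emb``).
* **Pairwise Interaction transformer** — two encoder-decoder attention
  layers that decode the promoter embedding against each pCRE's features
  (queries from the promoter, keys/values from the pCRE; bias-free
  projections), yielding one ``X_pair`` per interaction.
* **Regulation transformer** — stacked gated self-attention layers over the
  composite matrix ``X_comp`` whose first row is the promoter's TSS-bin
  embedding and whose remaining rows are the TSS-bin rows of each ``X_pair``
  (dummy zero rows for missing interactions). Normalized interaction
  frequencies enter as an additive bias ``gamma * B`` on the attention
  logits, and a sigmoid gate modulates the value path elementwise.

Row 0 of ``X_reg`` at each resolution is the regulatory embedding; the three
are concatenated and fed to a fully-connected head (classification logits,
a log2-expression scalar, or — in the Siamese differential variant — a log2
fold-change with shared-weight auxiliary expression heads).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Parameter, Tensor, concat, no_grad_fixup, scatter_rows
from .io_features import ConfigurationError, InputError, MARKS

__all__ = [
    "ModelConfig",
    "positional_encoding",
    "scaled_dot_attention",
    "Module",
    "Linear",
    "LayerNorm",
    "EmbeddingTransformer",
    "PairwiseTransformer",
    "RegulationTransformer",
    "Chromoformer",
    "ChromoformerDiff",
    "ablate_channels",
    "save_checkpoint",
    "load_checkpoint",
]

_MASK_NEG = -1e9  # additive logit for masked keys; underflows to weight 0.0


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the published configuration: model width 128 shared by all
    submodules, Embedding transformer with 2 heads of 64 dims, 2 pairwise
    layers (FFN hidden 256), 6 regulation layers with per-head width 32, at
    most 8 pCREs, and a 128-unit hidden layer in the prediction head.
    """

    channels: tuple[str, ...] = MARKS
    d_model: int = 128
    # Embedding transformer
    n_heads_emb: int = 2
    d_head_emb: int = 64
    ffn_emb: int = 128
    # Pairwise Interaction transformer
    n_layers_pair: int = 2
    n_heads_pair: int = 2
    d_head_pair: int = 64
    ffn_pair: int = 256
    # Regulation transformer
    n_layers_reg: int = 6
    n_heads_reg: int = 4
    d_head_reg: int = 32
    ffn_reg: int = 128
    gamma_init: float = 1.0
    bias_every_layer: bool = True  # re-inject gamma*B at every regulation layer
    use_pad_mask: bool = True  # mask dummy pCRE rows on the key side
    # geometry
    i_max: int = 8
    window: int = 40_000
    resolutions: tuple[int, ...] = (100, 500, 2000)
    # head / task
    head_hidden: int = 128
    task: str = "clf"
    embedding_only: bool = False
    dropout: float = 0.0
    layer_norm_eps: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        for name, m, dh in (
            ("embedding", self.n_heads_emb, self.d_head_emb),
            ("pairwise", self.n_heads_pair, self.d_head_pair),
            ("regulation", self.n_heads_reg, self.d_head_reg),
        ):
            if m * dh != self.d_model:
                raise ConfigurationError(
                    f"{name} heads x per-head dim = {m}x{dh} != model width {self.d_model}"
                )
        if self.d_model % 2 != 0:
            raise ConfigurationError("model width must be even for sinusoidal encoding")
        if self.task not in ("clf", "reg", "diff"):
            raise ConfigurationError(f"unknown task {self.task!r}")
        for r in self.resolutions:
            if self.window % r != 0:
                raise ConfigurationError(f"window {self.window} not divisible by {r}")

    def n_bins(self, resolution: int) -> int:
        return self.window // resolution

    def tss_bin(self, resolution: int) -> int:
        return self.n_bins(resolution) // 2

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def out_dim(self) -> int:
        return 2 if self.task == "clf" else 1

    @classmethod
    def scaled_down(cls, **overrides) -> "ModelConfig":
        """A light configuration for CPU-scale experiments on synthetic data:
        width 32, coarser 1000/2000/4000 bp bins over the same 40 kbp window,
        and 2 regulation layers."""
        base = dict(
            d_model=32,
            n_heads_emb=2,
            d_head_emb=16,
            ffn_emb=64,
            n_layers_pair=2,
            n_heads_pair=2,
            d_head_pair=16,
            ffn_pair=64,
            n_layers_reg=2,
            n_heads_reg=4,
            d_head_reg=8,
            ffn_reg=64,
            head_hidden=32,
            resolutions=(1000, 2000, 4000),
        )
        base.update(overrides)
        return cls(**base)


def positional_encoding(n: int, d: int) -> np.ndarray:
    """Sinusoidal positional encoding: P[i,2k]=sin(i/10000^(2k/d)),
    P[i,2k+1]=cos(i/10000^(2k/d)). Row inner products depend only on the
    positional distance |a-b|, which is what the attention layers exploit."""
    if d % 2 != 0:
        raise ConfigurationError("positional encoding dimension must be even")
    i = np.arange(n, dtype=np.float64)[:, None]
    k = np.arange(d // 2, dtype=np.float64)[None, :]
    angle = i / (10000.0 ** (2.0 * k / d))
    P = np.empty((n, d), dtype=np.float64)
    P[:, 0::2] = np.sin(angle)
    P[:, 1::2] = np.cos(angle)
    return P


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

class Module:
    """Minimal parameter container with named state for checkpoints."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        super().__setattr__(name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, child in self._children.items():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: Mapping[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise ConfigurationError(f"checkpoint/model parameter mismatch: {sorted(missing)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ConfigurationError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(d_in)
        self.W = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.b = Parameter(rng.uniform(-bound, bound, size=(d_out,))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Parameter(np.ones(d))
        self.bias = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.eps) * self.gain + self.bias


class FeedForward(Module):
    """Position-wise feed-forward: Linear -> ReLU -> Linear."""

    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

def scaled_dot_attention(
    Q: Tensor,
    K: Tensor,
    V: Tensor,
    scale_dim: int,
    bias: Tensor | None = None,
    gate: Tensor | None = None,
    key_mask: np.ndarray | None = None,
) -> tuple[Tensor, Tensor]:
    """softmax(Q K^T / sqrt(scale_dim) + bias) V, optionally gated.

    Q, K, V are (..., n, d_head). `bias` broadcasts onto the affinity matrix.
    `key_mask` is a boolean array (True = valid key) broadcastable to the
    affinity matrix; masked keys receive exactly zero weight. `gate` holds
    gate pre-activations; when given, the output is multiplied elementwise by
    sigmoid(gate). A query row whose keys are all masked degenerates to
    self-only attention (identity row) instead of NaN.
    """
    logits = (Q @ K.mT) * (1.0 / np.sqrt(float(scale_dim)))
    if bias is not None:
        logits = logits + bias
    degenerate = None
    if key_mask is not None:
        mask = np.broadcast_to(key_mask, logits.shape)
        logits = logits + np.where(mask, 0.0, _MASK_NEG)
        dead = ~mask.any(axis=-1)
        if dead.any():
            degenerate = dead
    weights = logits.softmax()
    if degenerate is not None:
        nq, nk = weights.shape[-2], weights.shape[-1]
        if nq != nk:
            raise InputError("every key is masked for a cross-attention query")
        w = weights.data.copy()
        eye = np.eye(nq)
        for row in np.argwhere(degenerate):
            w[tuple(row)] = eye[row[-1]]
        no_grad_fixup(weights, w)
    out = weights @ V
    if gate is not None:
        out = out * gate.sigmoid()
    return out, weights


def _split_heads(t: Tensor, n_heads: int, d_head: int) -> Tensor:
    b, n, _ = t.shape
    return t.reshape(b, n, n_heads, d_head).swapaxes(1, 2)


def _merge_heads(t: Tensor) -> Tensor:
    b, h, n, dh = t.shape
    return t.swapaxes(1, 2).reshape(b, n, h * dh)


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * keep


# ---------------------------------------------------------------------------
# Submodules (one instance per input resolution)
# ---------------------------------------------------------------------------

class EmbeddingTransformer(Module):
    """Single self-attention encoder layer over promoter bins."""

    def __init__(self, cfg: ModelConfig, n_bins: int, rng: np.random.Generator):
        super().__init__()
        d, H, dh = cfg.d_model, cfg.n_heads_emb, cfg.d_head_emb
        self.cfg = cfg
        self.n_bins = n_bins
        self.P = positional_encoding(n_bins, d)
        self.in_proj = Linear(cfg.n_channels, d, rng)
        self.Wq = Linear(d, H * dh, rng)
        self.Wk = Linear(d, H * dh, rng)
        self.Wv = Linear(d, H * dh, rng)
        self.ln1 = LayerNorm(d, cfg.layer_norm_eps)
        self.ffn = FeedForward(d, cfg.ffn_emb, rng)
        self.ln2 = LayerNorm(d, cfg.layer_norm_eps)

    def __call__(self, x_input: Tensor, rng=None, collect: bool = False):
        cfg = self.cfg
        if x_input.shape[1] != self.n_bins:
            raise InputError(f"expected {self.n_bins} bins, got {x_input.shape[1]}")
        h = self.in_proj(x_input) + self.P
        Q = _split_heads(self.Wq(h), cfg.n_heads_emb, cfg.d_head_emb)
        K = _split_heads(self.Wk(h), cfg.n_heads_emb, cfg.d_head_emb)
        V = _split_heads(self.Wv(h), cfg.n_heads_emb, cfg.d_head_emb)
        attn, w = scaled_dot_attention(Q, K, V, cfg.d_head_emb)
        h = self.ln1(h + _dropout(_merge_heads(attn), cfg.dropout, rng))
        out = self.ln2(h + _dropout(self.ffn(h), cfg.dropout, rng))
        return out, (w.data.copy() if collect else None)


class PairwiseLayer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d, H, dh = cfg.d_model, cfg.n_heads_pair, cfg.d_head_pair
        self.cfg = cfg
        # encoder-decoder attention: bias-free projections as specified
        self.Wq = Linear(d, H * dh, rng, bias=False)
        self.Wk = Linear(d, H * dh, rng, bias=False)
        self.Wv = Linear(d, H * dh, rng, bias=False)
        self.ln1 = LayerNorm(d, cfg.layer_norm_eps)
        self.ffn = FeedForward(d, cfg.ffn_pair, rng)
        self.ln2 = LayerNorm(d, cfg.layer_norm_eps)

    def __call__(self, x: Tensor, hm: Tensor, rng=None, collect: bool = False):
        cfg = self.cfg
        Q = _split_heads(self.Wq(x), cfg.n_heads_pair, cfg.d_head_pair)
        K = _split_heads(self.Wk(hm), cfg.n_heads_pair, cfg.d_head_pair)
        V = _split_heads(self.Wv(hm), cfg.n_heads_pair, cfg.d_head_pair)
        attn, w = scaled_dot_attention(Q, K, V, cfg.d_head_pair)
        x = self.ln1(x + _dropout(_merge_heads(attn), cfg.dropout, rng))
        x = self.ln2(x + _dropout(self.ffn(x), cfg.dropout, rng))
        return x, (w.data.copy() if collect else None)


class PairwiseTransformer(Module):
    """Stacked encoder-decoder layers decoding X_emb against one pCRE."""

    def __init__(self, cfg: ModelConfig, n_bins: int, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.n_bins = n_bins
        self.P = positional_encoding(n_bins, cfg.d_model)
        self.hm_proj = Linear(cfg.n_channels, cfg.d_model, rng)
        self.layers = [PairwiseLayer(cfg, rng) for _ in range(cfg.n_layers_pair)]

    def __call__(self, x_emb: Tensor, x_hm_raw: Tensor, rng=None, collect: bool = False):
        if x_hm_raw.shape[1] != x_emb.shape[1]:
            raise InputError("promoter and padded pCRE matrices must have equal bin counts")
        hm = self.hm_proj(x_hm_raw) + self.P
        x = x_emb
        maps = []
        for layer in self.layers:
            x, w = layer(x, hm, rng, collect)
            maps.append(w)
        return x, maps


class RegulationLayer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d, H, dh = cfg.d_model, cfg.n_heads_reg, cfg.d_head_reg
        self.cfg = cfg
        self.Wq = Linear(d, H * dh, rng, bias=False)
        self.Wk = Linear(d, H * dh, rng, bias=False)
        self.Wv = Linear(d, H * dh, rng, bias=False)
        self.Wg = Linear(d, H * dh, rng, bias=False)
        self.gamma = Parameter(np.array(cfg.gamma_init, dtype=np.float64))
        self.ln1 = LayerNorm(d, cfg.layer_norm_eps)
        self.ffn = FeedForward(d, cfg.ffn_reg, rng)
        self.ln2 = LayerNorm(d, cfg.layer_norm_eps)

    def __call__(
        self,
        x: Tensor,
        B_mat: np.ndarray | None,
        key_mask: np.ndarray | None,
        rng=None,
        gate_override: float | None = None,
        collect: bool = False,
    ):
        cfg = self.cfg
        Q = _split_heads(self.Wq(x), cfg.n_heads_reg, cfg.d_head_reg)
        K = _split_heads(self.Wk(x), cfg.n_heads_reg, cfg.d_head_reg)
        V = _split_heads(self.Wv(x), cfg.n_heads_reg, cfg.d_head_reg)
        if gate_override is None:
            G = _split_heads(self.Wg(x), cfg.n_heads_reg, cfg.d_head_reg)
        else:
            G = Tensor(np.full((x.shape[0], cfg.n_heads_reg, x.shape[1], cfg.d_head_reg), gate_override))
        bias = self.gamma * Tensor(B_mat) if B_mat is not None else None
        attn, w = scaled_dot_attention(Q, K, V, cfg.d_head_reg, bias=bias, gate=G, key_mask=key_mask)
        x = self.ln1(x + _dropout(_merge_heads(attn), cfg.dropout, rng))
        x = self.ln2(x + _dropout(self.ffn(x), cfg.dropout, rng))
        return x, (w.data.copy() if collect else None)


class RegulationTransformer(Module):
    """Stacked gated self-attention over the composite embedding matrix.

    No positional encoding: the pCRE rows form an unordered set; only row 0
    (the promoter) has a fixed identity. The frequency bias matrix B (row 0 =
    [0, f], zeros elsewhere) is injected at every layer by default — it
    encodes a static interaction prior — or only at the first layer when
    ``bias_every_layer`` is off.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.layers = [RegulationLayer(cfg, rng) for _ in range(cfg.n_layers_reg)]

    def __call__(
        self,
        x_comp: Tensor,
        f: np.ndarray,
        pad_mask: np.ndarray,
        rng=None,
        gate_override: float | None = None,
        collect: bool = False,
    ):
        cfg = self.cfg
        if np.any(f < 0):
            raise InputError("interaction frequencies must be non-negative")
        batch, n_tok = x_comp.shape[0], x_comp.shape[1]
        B_mat = np.zeros((batch, 1, n_tok, n_tok), dtype=np.float64)
        B_mat[:, 0, 0, 1:] = f
        key_mask = None
        if cfg.use_pad_mask:
            key_mask = pad_mask[:, None, None, :]
        x = x_comp
        maps = []
        for li, layer in enumerate(self.layers):
            use_bias = cfg.bias_every_layer or li == 0
            x, w = layer(x, B_mat if use_bias else None, key_mask, rng, gate_override, collect)
            maps.append(w)
        return x, maps


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

@dataclass
class ForwardOutput:
    prediction: Tensor  # (B, 2) logits for clf, (B, 1) scalar for reg
    bundle: dict | None = None


class Chromoformer(Module):
    """Multi-scale backbone + task head.

    With ``embedding_only`` the Pairwise and Regulation transformers are
    bypassed and the concatenated TSS-bin rows of ``X_emb`` feed the head
    directly (the interaction-blind ablation); the Embedding transformer is
    shared code between the two variants.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        embs, pairs, regs = {}, {}, {}
        for r in config.resolutions:
            n = config.n_bins(r)
            embs[r] = EmbeddingTransformer(config, n, rng)
            if not config.embedding_only:
                pairs[r] = PairwiseTransformer(config, n, rng)
                regs[r] = RegulationTransformer(config, rng)
        for r in config.resolutions:
            self._children[f"emb.{r}"] = embs[r]
            if not config.embedding_only:
                self._children[f"pair.{r}"] = pairs[r]
                self._children[f"reg.{r}"] = regs[r]
        self.embs, self.pairs, self.regs = embs, pairs, regs
        d_cat = len(config.resolutions) * config.d_model
        self.head1 = Linear(d_cat, config.head_hidden, rng)
        self.head2 = Linear(config.head_hidden, config.out_dim, rng)

    # -- encoding -------------------------------------------------------------

    def encode(
        self,
        batch: Mapping,
        rng: np.random.Generator | None = None,
        collect_attention: bool = False,
    ) -> tuple[Tensor, dict]:
        """Multi-scale regulatory embedding (B, 3*d) plus the embedding bundle."""
        cfg = self.config
        reg_vecs, prom_vecs = [], []
        bundle: dict = {"resolutions": {}, "gene_ids": batch.get("gene_ids")}
        f = batch["f"]
        pad_mask = batch["pad_mask"]
        for r in cfg.resolutions:
            prom = Tensor(batch["promoters"][r])
            if prom.shape[2] != cfg.n_channels:
                raise InputError(
                    f"expected {cfg.n_channels} channels, got {prom.shape[2]}"
                )
            x_emb, w_emb = self.embs[r](prom, rng, collect=collect_attention)
            mid = cfg.tss_bin(r)
            prom_vec = x_emb[:, mid, :]  # (B, d): the TSS-bin embedding
            res_info: dict = {"prom_vec": prom_vec.data.copy()}
            if collect_attention:
                res_info["attn_emb"] = w_emb
            if cfg.embedding_only:
                reg_vecs.append(prom_vec)
                prom_vecs.append(prom_vec)
                bundle["resolutions"][r] = res_info
                continue
            B, i_max = f.shape[0], cfg.i_max
            pcre = batch["pcres"][r]  # (B, i_max, n_r, C)
            n_r = pcre.shape[2]
            # decode the promoter against real pCREs only; dummy rows of the
            # composite matrix stay exactly zero
            real_idx = np.flatnonzero(pad_mask[:, 1:].reshape(-1))
            if len(real_idx):
                x_emb_rep = x_emb[real_idx // i_max]  # (n_real, n_r, d)
                pcre_real = Tensor(pcre.reshape(B * i_max, n_r, -1)[real_idx])
                x_pair_real, w_pair = self.pairs[r](
                    x_emb_rep, pcre_real, rng, collect=collect_attention
                )
                pair_mid = scatter_rows(
                    x_pair_real[:, mid, :], real_idx, B * i_max
                ).reshape(B, i_max, cfg.d_model)
            else:
                w_pair = []
                pair_mid = Tensor(np.zeros((B, i_max, cfg.d_model)))
            x_comp = concat([prom_vec.reshape(B, 1, cfg.d_model), pair_mid], axis=1)
            x_reg, w_regs = self.regs[r](x_comp, f, pad_mask, rng, collect=collect_attention)
            reg_vec = x_reg[:, 0, :]
            reg_vecs.append(reg_vec)
            prom_vecs.append(prom_vec)
            res_info["reg_vec"] = reg_vec.data.copy()
            if collect_attention:
                full_maps = []
                for w in w_pair:
                    full = np.zeros((B * i_max,) + w.shape[1:])
                    full[real_idx] = w
                    full_maps.append(full.reshape(B, i_max, *w.shape[1:]))
                res_info["attn_pair"] = full_maps
                res_info["attn_reg"] = w_regs
            bundle["resolutions"][r] = res_info
        z = concat(reg_vecs, axis=-1)
        bundle["promoter_vector"] = np.concatenate([p.data for p in prom_vecs], axis=-1)
        bundle["regulatory_vector"] = z.data.copy()
        return z, bundle

    def head(self, z: Tensor) -> Tensor:
        return self.head2(self.head1(z).relu())

    def forward(
        self,
        batch: Mapping,
        rng: np.random.Generator | None = None,
        collect_attention: bool = False,
    ) -> ForwardOutput:
        z, bundle = self.encode(batch, rng, collect_attention)
        return ForwardOutput(prediction=self.head(z), bundle=bundle)

    __call__ = forward


class ChromoformerDiff(Module):
    """Siamese differential variant: one shared backbone embeds two cell
    types' features for the same gene; the head predicts the log2 fold-change
    from the concatenated pair of multi-scale regulatory embeddings, and a
    single shared auxiliary head predicts each cell type's absolute log2
    expression (so swapping the two inputs swaps the auxiliary outputs)."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        if config.task != "diff":
            raise ConfigurationError("ChromoformerDiff requires task='diff'")
        self.config = config
        self.backbone = Chromoformer(replace(config, task="reg"))
        rng = np.random.default_rng(config.seed + 1)
        d_cat = len(config.resolutions) * config.d_model
        self.fc1 = Linear(2 * d_cat, config.head_hidden, rng)
        self.fc2 = Linear(config.head_hidden, 1, rng)
        self.aux1 = Linear(d_cat, config.head_hidden, rng)
        self.aux2 = Linear(config.head_hidden, 1, rng)

    def forward(self, batch_a: Mapping, batch_b: Mapping, rng=None) -> tuple[Tensor, Tensor, Tensor]:
        ca = batch_a["promoters"][self.config.resolutions[0]].shape[2]
        cb = batch_b["promoters"][self.config.resolutions[0]].shape[2]
        if ca != cb:
            raise InputError("the two cell types must share the channel set")
        za, _ = self.backbone.encode(batch_a, rng)
        zb, _ = self.backbone.encode(batch_b, rng)
        fold_change = self.fc2(self.fc1(concat([za, zb], axis=-1)).relu())
        aux_a = self.aux2(self.aux1(za).relu())
        aux_b = self.aux2(self.aux1(zb).relu())
        return fold_change, aux_a, aux_b

    __call__ = forward


def ablate_channels(dataset, channels_to_drop: Sequence[str]):
    """Remove histone-mark channels from a featurized dataset (HM ablation);
    a model built for the reduced channel set consumes the result."""
    return dataset.drop_channels(channels_to_drop)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Module, path, extra: dict | None = None) -> None:
    """Single-file checkpoint: weights + full config + featurization provenance."""
    path = Path(path)
    cfg = model.config
    meta = {
        "config": asdict(cfg),
        "model_class": type(model).__name__,
        "extra": extra or {},
    }
    state = {f"param:{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    z = np.load(path)
    meta = json.loads(bytes(z["__meta__"]).decode())
    cfg_d = meta["config"]
    cfg_d["channels"] = tuple(cfg_d["channels"])
    cfg_d["resolutions"] = tuple(cfg_d["resolutions"])
    cfg = ModelConfig(**cfg_d)
    cls = ChromoformerDiff if meta["model_class"] == "ChromoformerDiff" else Chromoformer
    model = cls(cfg)
    model.load_state_dict({k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")})
    return model, meta["extra"]
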