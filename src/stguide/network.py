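"""Neural architecture of the graph attention autoencoder.

Encoder: two stacked multi-head graph attention (GAT) layers.  For
head ``q`` with weight ``W_q`` and attention vector ``a_q``, the
attention logit between node ``i`` and neighbor ``j`` is

    e_ij^q = LeakyReLU( a_q^T [W_q h_i || W_q h_j] )

normalized by softmax over the neighborhood N_i (which includes ``i``
itself — the self-loop is added here, never stored in the graph).  The
layer output is the neighborhood-weighted sum of transformed features,
averaged over heads, passed through ELU (the final layer is linear so
the latent space is unconstrained).

Decoders: one linear + BatchNorm expression decoder per slice
(slice-specific normalization absorbs batch effects in reconstruction),
and an inner-product adjacency decoder sigmoid(z_i . z_j).  A linear
softmax classifier predicts annotation categories from the latent space
during supervised training.

Attention is materialized densely (n x n per head); instances are
desk-scale graphs, for which this is both fast and exact.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ._autograd import Adam, Tensor, glorot_uniform, parameter

__all__ = [
    "GATLayer",
    "Encoder",
    "SliceDecoder",
    "Classifier",
    "decode_adjacency",
    "StGuideNetwork",
]

NEG_SLOPE = 0.2  # LeakyReLU slope in attention logits
BN_EPS = 1e-5
BN_MOMENTUM = 0.1
_MASK_OFF = -1e30  # additive mask for non-neighbors; exp underflows to exactly 0


def attention_mask(adjacency: sp.spmatrix) -> np.ndarray:
    """Dense additive mask: 0 on edges and the diagonal, -inf-like elsewhere."""
    a = np.asarray(adjacency.todense(), dtype=bool)
    np.fill_diagonal(a, True)
    return np.where(a, 0.0, _MASK_OFF)


class GATLayer:
    """One multi-head graph attention layer (mean aggregation over heads)."""

    def __init__(self, in_dim: int, out_dim: int, n_heads: int, rng: np.random.Generator):
        self.in_dim, self.out_dim, self.n_heads = in_dim, out_dim, n_heads
        self.W = [parameter(glorot_uniform(rng, in_dim, out_dim)) for _ in range(n_heads)]
        # attention vector split into source/destination halves
        self.a_src = [
            parameter(glorot_uniform(rng, out_dim, 1, shape=(out_dim,)))
            for _ in range(n_heads)
        ]
        self.a_dst = [
            parameter(glorot_uniform(rng, out_dim, 1, shape=(out_dim,)))
            for _ in range(n_heads)
        ]
        self.last_attention: list[np.ndarray] | None = None

    def parameters(self) -> list[Tensor]:
        return self.W + self.a_src + self.a_dst

    def forward(self, h: Tensor, mask: np.ndarray, activation: str = "elu") -> Tensor:
        if h.shape[0] != mask.shape[0]:
            raise ValueError("feature rows do not match graph size")
        self.last_attention = []
        head_sum: Tensor | None = None
        for q in range(self.n_heads):
            hw = h @ self.W[q]  # (n, out)
            f_src = (hw * self.a_src[q]).sum(axis=1, keepdims=True)  # (n, 1)
            f_dst = (hw * self.a_dst[q]).sum(axis=1, keepdims=True)
            logits = (f_src + f_dst.T).leaky_relu(NEG_SLOPE) + Tensor(mask)
            attn = logits.softmax_rows()
            if np.any(np.isnan(attn.data)):
                raise FloatingPointError("NaN in attention coefficients")
            self.last_attention.append(attn.data.copy())
            out = attn @ hw
            head_sum = out if head_sum is None else head_sum + out
        avg = head_sum * (1.0 / self.n_heads)
        if activation == "elu":
            return avg.elu()
        if activation == "none":
            return avg
        raise ValueError(f"unknown activation {activation!r}")


class Encoder:
    """Stacked GAT layers; defaults: dims [m, 512, 10], 3 heads."""

    def __init__(self, dims: list[int], n_heads: int, rng: np.random.Generator):
        if len(dims) < 2:
            raise ValueError("encoder needs at least one layer")
        self.dims = list(dims)
        self.layers = [
            GATLayer(dims[i], dims[i + 1], n_heads, rng) for i in range(len(dims) - 1)
        ]

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        if x.shape[1] != self.dims[0]:
            raise ValueError(
                f"input has {x.shape[1]} features, encoder expects {self.dims[0]}"
            )
        h = x
        for i, layer in enumerate(self.layers):
            last = i == len(self.layers) - 1
            h = layer.forward(h, mask, activation="none" if last else "elu")
        return h


class SliceDecoder:
    """Linear + BatchNorm expression decoder for one slice.

    ``x' = gamma * (W z + b - mu) / sqrt(var + eps) + beta`` where in
    train mode ``mu``/``var`` are the slice-batch statistics (running
    averages tracked with momentum 0.1) and in eval mode the stored
    running statistics.
    """

    def __init__(self, latent_dim: int, n_genes: int, rng: np.random.Generator):
        self.W = parameter(glorot_uniform(rng, latent_dim, n_genes))
        self.b = parameter(np.zeros(n_genes))
        self.gamma = parameter(np.ones(n_genes))
        self.beta = parameter(np.zeros(n_genes))
        self.running_mean = np.zeros(n_genes)
        self.running_var = np.ones(n_genes)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b, self.gamma, self.beta]

    def forward(self, z: Tensor, mode: str = "train") -> Tensor:
        if z.shape[0] == 0:
            raise ValueError("empty slice block")
        h = z @ self.W + self.b
        if mode == "train":
            mu = h.mean(axis=0, keepdims=True)
            var = ((h - mu) ** 2.0).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - BN_MOMENTUM) * self.running_mean + BN_MOMENTUM * mu.data.ravel()
            )
            n = h.shape[0]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (
                (1 - BN_MOMENTUM) * self.running_var + BN_MOMENTUM * unbiased
            )
        elif mode == "eval":
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        else:
            raise ValueError(f"unknown mode {mode!r}")
        norm = (h - mu) * ((var + BN_EPS) ** -0.5)
        return self.gamma * norm + self.beta


class Classifier:
    """Linear softmax head over the latent space."""

    def __init__(self, latent_dim: int, n_classes: int, rng: np.random.Generator):
        self.W = parameter(glorot_uniform(rng, latent_dim, n_classes))

    def parameters(self) -> list[Tensor]:
        return [self.W]

    def forward(self, z: Tensor) -> Tensor:
        return (z @ self.W).softmax_rows()


def decode_adjacency(z: Tensor) -> Tensor:
    """Inner-product adjacency reconstruction: sigmoid(Z Z^T)."""
    if z.shape[0] == 0:
        raise ValueError("empty embedding")
    return (z @ z.T).sigmoid()


class StGuideNetwork:
    """Encoder + per-slice decoders (+ optional classifier) for one phase."""

    def __init__(
        self,
        n_genes: int,
        slice_ids: list[str],
        n_classes: int | None = None,
        hidden_dim: int = 512,
        latent_dim: int = 10,
        n_heads: int = 3,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.dims = [n_genes, hidden_dim, latent_dim]
        self.n_heads = n_heads
        self.encoder = Encoder(self.dims, n_heads, rng)
        self.decoders = {
            sid: SliceDecoder(latent_dim, n_genes, rng) for sid in slice_ids
        }
        self.classifier = (
            Classifier(latent_dim, n_classes, rng) if n_classes else None
        )

    def parameters(self) -> list[Tensor]:
        params = self.encoder.parameters()
        for dec in self.decoders.values():
            params.extend(dec.parameters())
        if self.classifier is not None:
            params.extend(self.classifier.parameters())
        return params

    def make_optimizer(self, lr: float, weight_decay: float) -> Adam:
        return Adam(self.parameters(), lr=lr, weight_decay=weight_decay)

    # -- checkpointing -------------------------------------------------
    CHECKPOINT_FORMAT = "stguide-checkpoint-v1"

    def save(self, path) -> None:
        """Single-file checkpoint: parameters plus architecture metadata."""
        import json

        meta = {
            "format": self.CHECKPOINT_FORMAT,
            "dims": self.dims,
            "n_heads": self.n_heads,
            "slice_ids": list(self.decoders),
            "n_classes": None
            if self.classifier is None
            else self.classifier.W.data.shape[1],
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "StGuideNetwork":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format") != cls.CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognized checkpoint format {meta.get('format')!r}")
            net = cls(
                n_genes=meta["dims"][0],
                slice_ids=meta["slice_ids"],
                n_classes=meta["n_classes"],
                hidden_dim=meta["dims"][1],
                latent_dim=meta["dims"][2],
                n_heads=meta["n_heads"],
            )
            net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return net

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self.encoder.layers):
            for q in range(layer.n_heads):
                state[f"enc.{li}.W.{q}"] = layer.W[q].data
                state[f"enc.{li}.a_src.{q}"] = layer.a_src[q].data
                state[f"enc.{li}.a_dst.{q}"] = layer.a_dst[q].data
        for sid, dec in self.decoders.items():
            for name in ("W", "b", "gamma", "beta"):
                state[f"dec.{sid}.{name}"] = getattr(dec, name).data
            state[f"dec.{sid}.running_mean"] = dec.running_mean
            state[f"dec.{sid}.running_var"] = dec.running_var
        if self.classifier is not None:
            state["clf.W"] = self.classifier.W.data
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.encoder.layers):
            for q in range(layer.n_heads):
                layer.W[q].data = np.asarray(state[f"enc.{li}.W.{q}"], dtype=np.float64)
                layer.a_src[q].data = np.asarray(state[f"enc.{li}.a_src.{q}"], dtype=np.float64)
                layer.a_dst[q].data = np.asarray(state[f"enc.{li}.a_dst.{q}"], dtype=np.float64)
        for sid, dec in self.decoders.items():
            dec.W.data = np.asarray(state[f"dec.{sid}.W"], dtype=np.float64)
            dec.b.data = np.asarray(state[f"dec.{sid}.b"], dtype=np.float64)
            dec.gamma.data = np.asarray(state[f"dec.{sid}.gamma"], dtype=np.float64)
            dec.beta.data = np.asarray(state[f"dec.{sid}.beta"], dtype=np.float64)
            dec.running_mean = np.asarray(state[f"dec.{sid}.running_mean"], dtype=np.float64)
            dec.running_var = np.asarray(state[f"dec.{sid}.running_var"], dtype=np.float64)
        if self.classifier is not None:
            self.classifier.W.data = np.asarray(state["clf.W"], dtype=np.float64)
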