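"""Spatial transformer classifier head: structured aggregation of token evidence.

Each token of the (stain-suppressed) feature grid is treated as a graph node
carrying its 2-D grid coordinate.  The head

1. embeds coordinates (sinusoidal by default) and adds them to projected
   token features:  ``h_i^(0) = f_i W_f + PE(p_i) W_p``;
2. splits node pairs into *adjacent* (Euclidean grid distance <= r, self
   loops included) and *non-adjacent* sets, so neighbourhood continuity and
   long-range interactions are modelled separately;
3. estimates a content-based dynamic structure once from ``h^(0)``:
   scaled dot-product scores are softmax-normalised within each set's
   support, and the two normalised matrices are fused by a learnable
   coefficient ``lambda = sigmoid(theta)`` into a single matrix ``A_hat``
   that stays fixed across layers;
4. runs L cooperative update layers: a graph-transformer step whose fresh
   full softmax attention is multiplied elementwise by ``A_hat`` (no row
   renormalisation by default — a ``renormalize`` switch restores row
   stochasticity for experimentation), followed by a dynamic
   graph-convolution step ``relu((A_hat h) W_g) + h``;
5. pools the final node states with a tanh-bottleneck attention readout and
   applies a linear softmax classifier for the two classes (Normal, OSCC).

Rows of the masked softmax whose support is empty (e.g. the non-adjacent set
of a single-token grid) are all-zero rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Module, Linear, Parameter, masked_softmax, softmax

__all__ = [
    "SpatialTopology",
    "DynamicStructure",
    "ReadoutResult",
    "Prediction",
    "sinusoidal_encoding",
    "build_topology",
    "SpatialHead",
]


@dataclass
class SpatialTopology:
    """Radius-based dual topology on the token grid."""

    distances: np.ndarray  # (N, N) Euclidean, token-grid units
    radius: float
    adjacent: np.ndarray  # (N, N) binary, d_ij <= r (diagonal included)
    nonadjacent: np.ndarray  # complement: 1 - adjacent


@dataclass
class DynamicStructure:
    """Content-based structure estimate computed once from h^(0)."""

    scores: np.ndarray  # (N, N) scaled dot products
    norm_adj: np.ndarray  # softmax of scores on the adjacent support
    norm_non: np.ndarray  # softmax of scores on the non-adjacent support
    fused: np.ndarray  # lambda * norm_adj + (1 - lambda) * norm_non
    lam: float


@dataclass
class ReadoutResult:
    attention: np.ndarray  # (N,), nonnegative, sums to 1
    pooled: np.ndarray  # (d,), convex combination of final node states


@dataclass
class Prediction:
    probabilities: np.ndarray  # (2,), softmax output; index 1 = OSCC
    structure: DynamicStructure | None = None
    readout: ReadoutResult | None = None

    @property
    def oscc_score(self) -> float:
        return float(self.probabilities[1])


def sinusoidal_encoding(coords: np.ndarray, dim: int) -> np.ndarray:
    """Fixed 2-D sin/cos positional encoding; `dim` must be divisible by 4.

    Half the dimensions encode the row, half the column; at the origin all
    sine components are 0 and all cosine components are 1.
    """
    if dim % 4:
        raise ValueError("positional encoding dim must be divisible by 4")
    coords = np.asarray(coords, dtype=np.float64)
    half = dim // 2
    n_freq = half // 2
    freqs = 1.0 / (10000.0 ** (np.arange(n_freq) / n_freq))
    out = []
    for axis in range(2):
        ang = coords[:, axis : axis + 1] * freqs[None, :]
        out.append(np.sin(ang))
        out.append(np.cos(ang))
    return np.concatenate(out, axis=1)


def build_topology(coords: np.ndarray, radius: float) -> SpatialTopology:
    """Adjacent/non-adjacent masks from Euclidean grid distances.

    Self-loops fall in the adjacent set (d_ii = 0 <= r); the two masks are
    exact complements.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = np.asarray(coords, dtype=np.float64)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    adj = (dist <= radius).astype(np.float64)
    return SpatialTopology(distances=dist, radius=float(radius), adjacent=adj,
                           nonadjacent=1.0 - adj)


class SpatialHead(Module):
    """Graph-transformer aggregation head over coordinate-aware tokens.

    Parameters
    ----------
    in_channels:
        Channel dimension C of the incoming fused token features.
    dim:
        Node state / projection dimension d (default 128).
    depth:
        Number of cooperative update layers L (default 2).
    radius:
        Neighbourhood radius r in token-grid units (default 1.5: the
        8-neighbourhood including diagonals).
    pe:
        "sinusoidal" (fixed, default) or "learnable" (per-axis embedding
        tables up to `max_grid` positions).
    renormalize:
        If True, rows of the elementwise product A_hat * softmax in the
        graph-transformer step are rescaled to sum to one.
    n_classes:
        Output classes (2: Normal vs OSCC).
    """

    def __init__(self, in_channels: int, dim: int = 128, depth: int = 2,
                 radius: float = 1.5, pe: str = "sinusoidal",
                 renormalize: bool = False, max_grid: int = 64,
                 n_classes: int = 2, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if pe not in ("sinusoidal", "learnable"):
            raise ValueError(f"unknown positional encoding mode {pe!r}")
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.depth = depth
        self.radius = radius
        self.pe_mode = pe
        self.renormalize = renormalize
        self.wp = Linear(dim, dim, rng, bias=False)  # PE projection
        self.wf = Linear(in_channels, dim, rng, bias=False)  # feature projection
        if pe == "learnable":
            self.pe_row = Parameter(rng.normal(0, 0.02, size=(max_grid, dim // 2)))
            self.pe_col = Parameter(rng.normal(0, 0.02, size=(max_grid, dim // 2)))
        # structure estimation projections (used once, on h0)
        self.struct_wq = Linear(dim, dim, rng, bias=False)
        self.struct_wk = Linear(dim, dim, rng, bias=False)
        self.lambda_logit = Parameter(np.zeros(1))  # lambda = sigmoid(0) = 0.5
        # per-layer projections
        self.layer_wq = [Linear(dim, dim, rng, bias=False) for _ in range(depth)]
        self.layer_wk = [Linear(dim, dim, rng, bias=False) for _ in range(depth)]
        self.layer_wv = [Linear(dim, dim, rng, bias=False) for _ in range(depth)]
        self.layer_wg = [Linear(dim, dim, rng, bias=False) for _ in range(depth)]
        # readout and classifier
        self.wa = Linear(dim, dim, rng, bias=False)
        self.u = Parameter(rng.normal(0, 1.0 / np.sqrt(dim), size=(dim,)))
        self.classifier = Linear(dim, n_classes, rng)

    # ---- pieces ---------------------------------------------------------
    @property
    def lam(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.lambda_logit.data[0])))

    def embed_positions(self, coords: np.ndarray) -> Tensor:
        """(N,2) grid coordinates -> (N,d) geometric embeddings e_i = PE(p_i) W_p."""
        coords = np.asarray(coords, dtype=int)
        if self.pe_mode == "sinusoidal":
            pe = Tensor(sinusoidal_encoding(coords, self.dim))
        else:
            row = self.pe_row[coords[:, 0]]
            col = self.pe_col[coords[:, 1]]
            pe = _concat_cols(row, col)
        return self.wp(pe)

    def init_nodes(self, fused: Tensor, coords: np.ndarray) -> Tensor:
        """h^(0) = fused W_f + e, batched over (B,N,C)."""
        return self.wf(fused) + self.embed_positions(coords)

    def similarity_scores(self, h0: Tensor) -> Tensor:
        """S = (h0 Wq)(h0 Wk)^T / sqrt(d), batched (B,N,d) -> (B,N,N)."""
        q = self.struct_wq(h0)
        k = self.struct_wk(h0)
        return (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dim))

    def estimate_structure(self, h0: Tensor, topology: SpatialTopology) -> Tensor:
        """Masked dual softmax + lambda fusion; computed once from h^(0)."""
        s = self.similarity_scores(h0)
        a_adj = masked_softmax(s, topology.adjacent[None], axis=-1)
        a_non = masked_softmax(s, topology.nonadjacent[None], axis=-1)
        lam = self.lambda_logit.sigmoid()
        return lam * a_adj + (1.0 - lam) * a_non

    def update_layer(self, h: Tensor, a_hat: Tensor, layer: int) -> Tensor:
        """One cooperative update: masked graph attention then graph convolution."""
        q = self.layer_wq[layer](h)
        k = self.layer_wk[layer](h)
        v = self.layer_wv[layer](h)
        attn = softmax((q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dim)), axis=-1)
        eff = a_hat * attn
        if self.renormalize:
            eff = eff / (eff.sum(axis=-1, keepdims=True) + 1e-12)
        h_half = eff @ v
        agg = (a_hat @ h_half) @ self.layer_wg[layer].weight
        return agg.relu() + h

    def attend_readout(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """Tanh-bottleneck attention pooling: weights (B,N) and pooled states (B,d)."""
        gates = self.wa(h).tanh() @ self.u  # (B, N)
        a = softmax(gates, axis=-1)
        z = (a.reshape(*a.shape, 1) * h).sum(axis=-2)
        return a, z

    def forward(self, fused: Tensor, coords: np.ndarray) -> Tensor:
        """(B,N,C) fused features + (N,2) coords -> (B,2) class probabilities."""
        topology = build_topology(coords, self.radius)
        h = self.init_nodes(fused, coords)
        a_hat = self.estimate_structure(h, topology)
        for layer in range(self.depth):
            h = self.update_layer(h, a_hat, layer)
        _, z = self.attend_readout(h)
        return softmax(self.classifier(z), axis=-1)

    # ---- single-image convenience with inspectable intermediates ---------
    def head_forward(self, fused: np.ndarray, coords: np.ndarray,
                     return_intermediates: bool = False) -> Prediction:
        """Classify one image's fused token matrix (N,C)."""
        fused = np.asarray(fused, dtype=np.float64)
        topology = build_topology(coords, self.radius)
        x = Tensor(fused[None])
        h = self.init_nodes(x, coords)
        s = self.similarity_scores(h)
        a_adj = masked_softmax(s, topology.adjacent[None], axis=-1)
        a_non = masked_softmax(s, topology.nonadjacent[None], axis=-1)
        lam = self.lam
        a_hat = Tensor(lam * a_adj.numpy() + (1.0 - lam) * a_non.numpy())
        for layer in range(self.depth):
            h = self.update_layer(h, a_hat, layer)
        a, z = self.attend_readout(h)
        probs = softmax(self.classifier(z), axis=-1).numpy()[0]
        structure = readout = None
        if return_intermediates:
            structure = DynamicStructure(
                scores=s.numpy()[0], norm_adj=a_adj.numpy()[0],
                norm_non=a_non.numpy()[0], fused=a_hat.numpy()[0], lam=lam,
            )
            readout = ReadoutResult(attention=a.numpy()[0], pooled=z.numpy()[0])
        return Prediction(probabilities=probs, structure=structure, readout=readout)


def _concat_cols(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two (N, k) tensors along columns, autodiff-aware."""
    n, ka = a.shape
    _, kb = b.shape
    out = Tensor(np.concatenate([a.numpy(), b.numpy()], axis=1), parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, :ka])
        if b.requires_grad:
            b._accumulate(g[:, ka:])

    out._backward = backward
    return out
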