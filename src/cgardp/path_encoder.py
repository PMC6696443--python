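"""The path branch: bidirectional GRU over paths with path-level attention.

Each drug-to-disease path is a sequence of node feature vectors.  A gated
recurrent unit (GRU) reads the sequence in both directions from zero
initial states; the path representation is the concatenation of the two
final hidden states.  Because different paths contribute differently to an
association, a learned attention layer scores each path representation
(tanh projection against a context vector, softmax across the pair's
paths) and pools them into a single vector ``g`` for the pair.

GRU cell (per step, input x_t, previous state h):

    z_t = sigmoid(W_z x_t + U_z h + b_z)        update gate
    r_t = sigmoid(W_r x_t + U_r h + b_r)        reset gate
    h~  = tanh(W_h x_t + r_t * (U_h h) + b_h)   candidate state
    h_t = (1 - z_t) * h + z_t * h~

With z_t -> 1 the state jumps to the candidate; with z_t -> 0 it carries
the previous state through; with r_t = 0 the candidate ignores all history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "GruConfig",
    "GruParams",
    "AttentionParams",
    "PathRepresentation",
    "gru_step",
    "encode_path",
    "attend",
    "gru_step_t",
    "gru_sequence_t",
    "attend_t",
    "DEFAULT_HIDDEN_DIM",
    "DEFAULT_ATTENTION_DIM",
]

DEFAULT_HIDDEN_DIM = 32
DEFAULT_ATTENTION_DIM = 32


@dataclass
class GruConfig:
    hidden_dim: int = DEFAULT_HIDDEN_DIM
    attention_dim: int = DEFAULT_ATTENTION_DIM

    def validate(self) -> None:
        if self.hidden_dim < 1 or self.attention_dim < 1:
            raise ValueError("hidden_dim and attention_dim must be positive")


@dataclass
class GruParams:
    """One direction's gate weights.

    Input weights ``W_*`` are (input_dim, hidden); recurrent weights
    ``U_*`` are (hidden, hidden); biases are (hidden,).
    """

    W_z: Tensor
    U_z: Tensor
    b_z: Tensor
    W_r: Tensor
    U_r: Tensor
    b_r: Tensor
    W_h: Tensor
    U_h: Tensor
    b_h: Tensor

    @property
    def hidden_dim(self) -> int:
        return self.U_z.value.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_z.value.shape[0]

    def tensors(self) -> dict[str, Tensor]:
        return {k: getattr(self, k) for k in
                ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r", "W_h", "U_h", "b_h")}


@dataclass
class AttentionParams:
    """Path-importance scorer: projection W_t/b_t and context vector u_p."""

    W_t: Tensor  # (2*hidden, attention_dim)
    b_t: Tensor  # (attention_dim,)
    u_p: Tensor  # (attention_dim,)

    def tensors(self) -> dict[str, Tensor]:
        return {"W_t": self.W_t, "b_t": self.b_t, "u_p": self.u_p}


@dataclass
class PathRepresentation:
    path_vectors: np.ndarray  # (n_paths, 2*hidden)
    attention: np.ndarray  # (n_paths,)
    g: np.ndarray  # (2*hidden,)


# ---- Tensor-level building blocks (shared by training and inference) ----


def gru_step_t(x: Tensor, h: Tensor, p: GruParams) -> Tensor:
    """One GRU step on a batch: x (B, F), h (B, H) -> (B, H)."""
    z = (x @ p.W_z + h @ p.U_z + p.b_z).sigmoid()
    r = (x @ p.W_r + h @ p.U_r + p.b_r).sigmoid()
    h_tilde = (x @ p.W_h + r * (h @ p.U_h) + p.b_h).tanh()
    return (1.0 - z) * h + z * h_tilde


def gru_sequence_t(steps: list[np.ndarray], p: GruParams) -> Tensor:
    """Run the GRU over a batch of equal-length sequences.

    ``steps[t]`` is the (B, F) input at time t; returns the final (B, H)
    hidden state, starting from zeros.
    """
    B = steps[0].shape[0]
    h: Tensor = ad.constant(np.zeros((B, p.hidden_dim)))
    for x_t in steps:
        h = gru_step_t(ad.constant(x_t), h, p)
    return h


def attend_t(path_vecs: Tensor, p: AttentionParams) -> tuple[Tensor, Tensor]:
    """Attention pooling over one pair's paths: (k, 2H) -> ((1, 2H), (k,))."""
    u = (path_vecs @ p.W_t + p.b_t).tanh()
    scores = u @ p.u_p
    alpha = ad.softmax(scores, axis=-1)
    g = alpha.reshape(1, -1) @ path_vecs
    return g, alpha


# ---- numpy-facing operations ----


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, params: GruParams) -> np.ndarray:
    """Single-vector GRU step: x_t (F,), h_prev (H,) -> h_t (H,)."""
    x_t, h_prev = np.asarray(x_t, float), np.asarray(h_prev, float)
    if x_t.shape != (params.input_dim,) or h_prev.shape != (params.hidden_dim,):
        raise ValueError(
            f"expected x_t {(params.input_dim,)}, h_prev {(params.hidden_dim,)}; "
            f"got {x_t.shape}, {h_prev.shape}"
        )
    out = gru_step_t(ad.constant(x_t[None]), ad.constant(h_prev[None]), params)
    return out.value[0]


def encode_path(
    path: np.ndarray, fwd: GruParams, bwd: GruParams
) -> np.ndarray:
    """Bidirectional encoding of one path's (L, F) node features.

    Returns the concatenation ``[h_forward_final || h_backward_final]``
    of length 2 * hidden_dim.
    """
    feats = np.asarray(path, dtype=float)
    if feats.ndim != 2 or feats.shape[0] < 2:
        raise ValueError("a path needs at least 2 nodes of features")
    h_f = gru_sequence_t([feats[t][None] for t in range(feats.shape[0])], fwd)
    h_b = gru_sequence_t([feats[t][None] for t in range(feats.shape[0] - 1, -1, -1)], bwd)
    return np.concatenate([h_f.value[0], h_b.value[0]])


def attend(path_vecs: list[np.ndarray], params: AttentionParams) -> PathRepresentation:
    """Softmax-attention pooling of a pair's path vectors."""
    if len(path_vecs) == 0:
        raise ValueError("attend requires at least one path vector")
    H = ad.constant(np.stack(path_vecs))
    g, alpha = attend_t(H, params)
    return PathRepresentation(H.value, alpha.value, g.value[0])
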