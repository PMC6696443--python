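"""Per-pair feature matrices.

For a drug ``i`` and disease ``j`` the model consumes a 2 x (Nr + Nd)
matrix ``X`` stacking the drug's eigenvector over the disease's:

* row 0: ``[R[i, :] || A[i, :]]`` — the drug's similarity to every drug
  followed by its association with every disease;
* row 1: ``[A[:, j]^T || D[j, :]]`` — every drug's association with the
  disease followed by the disease's similarity to every disease.

Before convolution the matrix is zero-padded by ``p_r`` rows and ``p_c``
columns on each border so boundary entries are seen by full filter windows.

When building features for a *known* association (``A[i, j] = 1``) the two
entries of X that directly encode that label (column ``Nr + j`` of row 0
and column ``i`` of row 1) can be zeroed (``mask_known``) so the model
cannot read its training label off the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import HeteroNetwork

__all__ = ["PairFeatureMatrix", "build_pair_matrix", "pad", "DEFAULT_PADDING"]

DEFAULT_PADDING = (1, 10)


@dataclass
class PairFeatureMatrix:
    drug_index: int
    disease_index: int
    X: np.ndarray
    X_padded: np.ndarray
    padding: tuple[int, int]


def pad(X: np.ndarray, p: tuple[int, int]) -> np.ndarray:
    """Zero-pad with ``p = (p_r, p_c)`` layers on every border."""
    p_r, p_c = p
    if p_r < 0 or p_c < 0:
        raise ValueError("padding must be nonnegative")
    if p_r == 0 and p_c == 0:
        return X
    return np.pad(X, ((p_r, p_r), (p_c, p_c)))


def build_pair_matrix(
    net: HeteroNetwork,
    i: int,
    j: int,
    mask_known: bool = True,
    padding: tuple[int, int] = DEFAULT_PADDING,
) -> PairFeatureMatrix:
    """Assemble X (and its padded form) for drug ``i`` and disease ``j``."""
    nr, nd = net.n_drugs, net.n_diseases
    if not 0 <= i < nr:
        raise IndexError(f"drug index {i} out of range [0, {nr})")
    if not 0 <= j < nd:
        raise IndexError(f"disease index {j} out of range [0, {nd})")
    X = np.empty((2, nr + nd))
    X[0, :nr] = net.R[i, :]
    X[0, nr:] = net.A[i, :]
    X[1, :nr] = net.A[:, j]
    X[1, nr:] = net.D[j, :]
    if mask_known and net.A[i, j] == 1.0:
        X[0, nr + j] = 0.0
        X[1, i] = 0.0
    return PairFeatureMatrix(i, j, X, pad(X, padding), padding)
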