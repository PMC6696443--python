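"""The CNN branch: local pair representation from the feature matrix.

The padded per-pair matrix X' passes through a stack of valid convolutions
(ReLU activation) with non-overlapping max pooling after each, is
flattened, and maps through a fully connected layer with an elementwise
sigmoid to the local representation ``c`` of the drug-disease pair.

Defaults follow the reference configuration: two convolution layers with
16 and 32 filters of shape 3 x 20, padding (1, 10) applied once to X, and
a (2, 2) pooling window.  Deeper layers reuse the same filter/pool
settings; filters (and pooling windows) larger than the current feature
map are clamped to it, so the stack degrades gracefully on tiny networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .pair_features import PairFeatureMatrix

__all__ = [
    "ConvConfig",
    "LocalRepresentation",
    "conv_layer",
    "max_pool",
    "local_forward",
    "plan_conv_stack",
    "local_forward_batch",
]


@dataclass
class ConvConfig:
    filter_height: int = 3
    filter_width: int = 20
    n_filters_per_layer: tuple[int, ...] = (16, 32)
    padding: tuple[int, int] = (1, 10)
    pool_window: tuple[int, int] = (2, 2)
    fc_out_dim: int = 32

    def validate(self) -> None:
        if min(self.filter_height, self.filter_width, self.fc_out_dim) < 1:
            raise ValueError("filter dims and fc_out_dim must be positive")
        if not self.n_filters_per_layer or min(self.n_filters_per_layer) < 1:
            raise ValueError("need at least one positive filter count")
        if min(self.padding) < 0 or min(self.pool_window) < 1:
            raise ValueError("padding must be >= 0, pool window >= 1")


@dataclass
class LocalRepresentation:
    c: np.ndarray
    intermediate_shapes: list[tuple[int, ...]] = field(default_factory=list)


@dataclass
class _LayerPlan:
    in_channels: int
    n_filters: int
    kernel: tuple[int, int]
    pool: tuple[int, int]
    out_shape: tuple[int, int]  # spatial shape after pooling


def plan_conv_stack(
    cfg: ConvConfig, input_shape: tuple[int, int]
) -> tuple[list[_LayerPlan], int]:
    """Resolve per-layer kernel/pool geometry for a given padded input.

    Returns the layer plans and the flattened dimension feeding the fully
    connected layer.
    """
    cfg.validate()
    h, w = input_shape
    plans: list[_LayerPlan] = []
    channels = 1
    for n_filt in cfg.n_filters_per_layer:
        kh, kw = min(cfg.filter_height, h), min(cfg.filter_width, w)
        h, w = h - kh + 1, w - kw + 1
        ph, pw = min(cfg.pool_window[0], h), min(cfg.pool_window[1], w)
        h, w = h // ph, w // pw
        plans.append(_LayerPlan(channels, n_filt, (kh, kw), (ph, pw), (h, w)))
        channels = n_filt
    return plans, channels * h * w


def conv_layer(X_padded: np.ndarray, filters: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid convolution + ReLU of one (possibly multi-channel) input.

    ``X_padded``: (H, W) or (C, H, W); ``filters``: (n_filters, C, kh, kw)
    or (n_filters, kh, kw) for single-channel input; ``bias``: (n_filters,).
    Output: (n_filters, H-kh+1, W-kw+1).
    """
    x = np.asarray(X_padded, dtype=float)
    if x.ndim == 2:
        x = x[None]
    w = np.asarray(filters, dtype=float)
    if w.ndim == 3:
        w = w[:, None]
    out = ad.conv2d(ad.constant(x[None]), ad.constant(w), ad.constant(bias)).relu()
    return out.value[0]


def max_pool(
    Zconv: np.ndarray,
    window: tuple[int, int],
    stride: tuple[int, int] | None = None,
) -> np.ndarray:
    """Max pooling over feature maps (C, H, W) or (H, W).

    Stride defaults to the window (non-overlapping); trailing windows that
    do not fit are dropped.  An explicit stride different from the window
    is evaluated with a direct sliding maximum.
    """
    z = np.asarray(Zconv, dtype=float)
    squeeze = z.ndim == 2
    if squeeze:
        z = z[None]
    if stride is None or tuple(stride) == tuple(window):
        out = ad.max_pool2d(ad.constant(z[None]), window).value[0]
    else:
        sh, sw = stride
        ph, pw = min(window[0], z.shape[1]), min(window[1], z.shape[2])
        rows = range(0, z.shape[1] - ph + 1, sh)
        cols = range(0, z.shape[2] - pw + 1, sw)
        out = np.array(
            [
                [[z[c, r : r + ph, s : s + pw].max() for s in cols] for r in rows]
                for c in range(z.shape[0])
            ]
        )
    return out[0] if squeeze else out


def local_forward_batch(
    xp: Tensor,
    conv_params: list[tuple[Tensor, Tensor]],
    W_l: Tensor,
    cfg: ConvConfig,
    plans: list[_LayerPlan],
    dropout_mask: np.ndarray | None = None,
) -> Tensor:
    """Tensor-level forward of the CNN branch for a batch.

    ``xp``: (B, 1, H, W) padded inputs; ``conv_params``: per-layer
    (filters, bias); ``dropout_mask``: optional pre-scaled mask applied to
    the flattened convolution output during training (inverted dropout).
    """
    z = xp
    for (w, b), plan in zip(conv_params, plans):
        z = ad.conv2d(z, w, b).relu()
        z = ad.max_pool2d(z, plan.pool)
    flat = z.reshape(z.shape[0], -1)
    if dropout_mask is not None:
        flat = flat * ad.constant(dropout_mask)
    return (flat @ W_l).sigmoid()


def local_forward(
    pfm: PairFeatureMatrix, params, cfg: ConvConfig
) -> LocalRepresentation:
    """Numpy-facing single-pair forward pass (inference; dropout off).

    ``params`` is a :class:`~cgardp.trainer.ModelParams` (or anything with
    ``conv_layers`` and ``W_l`` tensors shaped for this configuration).
    """
    xp = pfm.X_padded
    plans, flat_dim = plan_conv_stack(cfg, xp.shape)
    if params.W_l.value.shape != (flat_dim, cfg.fc_out_dim):
        raise ValueError(
            f"W_l shape {params.W_l.value.shape} inconsistent with planned "
            f"flatten dim {flat_dim} and fc_out_dim {cfg.fc_out_dim}"
        )
    shapes = [xp.shape]
    out = local_forward_batch(
        ad.constant(xp[None, None]), params.conv_layers, params.W_l, cfg, plans
    )
    for plan in plans:
        shapes.append((plan.n_filters,) + plan.out_shape)
    return LocalRepresentation(out.value[0], shapes)
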