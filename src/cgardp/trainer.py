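"""Model parameters, the dual-head scoring/loss scheme, and training glue.

The two branch representations are mapped through separate softmax heads:
``score_c = softmax(W_c c + b_c)`` for the CNN branch and
``score_g = softmax(W_v g + b_v)`` for the path branch.  Component 1 of
each two-vector is the probability that the pair is associated.  Each head
carries its own binary cross-entropy and the total loss is the convex
combination ``alpha1 * loss1 + (1 - alpha1) * loss2``; the final score is
the same convex combination of the two head outputs.  Pairs with no
connecting path are scored (and trained) on the CNN head alone.

Training pairs are the known associations plus an equal-by-default number
of unknown pairs sampled uniformly without replacement as negatives.
Optimization uses Adam on the mean combined loss, with inverted dropout
on the flattened convolution output and on the path vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .local_encoder import ConvConfig, plan_conv_stack
from .netio import HeteroNetwork
from .path_encoder import AttentionParams, GruConfig, GruParams

__all__ = [
    "TrainConfig",
    "ModelParams",
    "init_model_params",
    "pair_score",
    "combined_loss",
    "sample_training_pairs",
    "train",
    "Adam",
    "ASSOCIATED",
]

# softmax component carrying "the pair is associated"
ASSOCIATED = 1


@dataclass
class TrainConfig:
    alpha1: float = 0.5
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    neg_ratio: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.alpha1 <= 1.0:
            raise ValueError("alpha1 must be in [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid learning_rate/batch_size/epochs")
        if self.neg_ratio <= 0:
            raise ValueError("neg_ratio must be positive")


@dataclass
class ModelParams:
    """Every learnable tensor of both encoders, attention, and the heads."""

    conv_layers: list[tuple[Tensor, Tensor]]  # per layer: (filters, bias)
    W_l: Tensor
    gru_fwd: GruParams
    gru_bwd: GruParams
    attention: AttentionParams
    W_c: Tensor
    b_c: Tensor
    W_v: Tensor
    b_v: Tensor
    input_shape: tuple[int, int] = (0, 0)  # (n_drugs, n_diseases) trained on

    def named_tensors(self) -> dict[str, Tensor]:
        named: dict[str, Tensor] = {}
        for li, (w, b) in enumerate(self.conv_layers):
            named[f"conv{li}_W"] = w
            named[f"conv{li}_b"] = b
        named["W_l"] = self.W_l
        for tag, gru in (("fwd", self.gru_fwd), ("bwd", self.gru_bwd)):
            for k, t in gru.tensors().items():
                named[f"gru_{tag}_{k}"] = t
        for k, t in self.attention.tensors().items():
            named[f"att_{k}"] = t
        named.update(W_c=self.W_c, b_c=self.b_c, W_v=self.W_v, b_v=self.b_v)
        return named

    def check_finite(self) -> None:
        for name, t in self.named_tensors().items():
            if not np.isfinite(t.value).all():
                raise FloatingPointError(f"non-finite values in parameter {name}")

    def save(self, path: str | Path) -> None:
        arrays = {k: t.value for k, t in self.named_tensors().items()}
        arrays["input_shape"] = np.array(self.input_shape)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
        conv_layers = []
        li = 0
        while f"conv{li}_W" in arrays:
            conv_layers.append(
                (ad.parameter(arrays[f"conv{li}_W"]), ad.parameter(arrays[f"conv{li}_b"]))
            )
            li += 1

        def gru(tag: str) -> GruParams:
            return GruParams(
                **{k: ad.parameter(arrays[f"gru_{tag}_{k}"])
                   for k in ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r",
                             "W_h", "U_h", "b_h")}
            )

        return cls(
            conv_layers=conv_layers,
            W_l=ad.parameter(arrays["W_l"]),
            gru_fwd=gru("fwd"),
            gru_bwd=gru("bwd"),
            attention=AttentionParams(
                W_t=ad.parameter(arrays["att_W_t"]),
                b_t=ad.parameter(arrays["att_b_t"]),
                u_p=ad.parameter(arrays["att_u_p"]),
            ),
            W_c=ad.parameter(arrays["W_c"]),
            b_c=ad.parameter(arrays["b_c"]),
            W_v=ad.parameter(arrays["W_v"]),
            b_v=ad.parameter(arrays["b_v"]),
            input_shape=tuple(int(v) for v in arrays["input_shape"]),
        )


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return ad.parameter(rng.uniform(-bound, bound, size=shape))


def init_model_params(
    n_drugs: int,
    n_diseases: int,
    conv_cfg: ConvConfig,
    gru_cfg: GruConfig,
    rng: np.random.Generator,
) -> ModelParams:
    """Seeded fan-in-scaled uniform initialization for a given network size."""
    conv_cfg.validate()
    gru_cfg.validate()
    feat = n_drugs + n_diseases
    padded = (2 + 2 * conv_cfg.padding[0], feat + 2 * conv_cfg.padding[1])
    plans, flat_dim = plan_conv_stack(conv_cfg, padded)
    conv_layers = []
    for plan in plans:
        fan = plan.in_channels * plan.kernel[0] * plan.kernel[1]
        conv_layers.append(
            (
                _uniform(rng, (plan.n_filters, plan.in_channels) + plan.kernel, fan),
                ad.parameter(np.zeros(plan.n_filters)),
            )
        )
    H, att = gru_cfg.hidden_dim, gru_cfg.attention_dim

    def gru() -> GruParams:
        kw = {}
        for gate in ("z", "r", "h"):
            kw[f"W_{gate}"] = _uniform(rng, (feat, H), feat)
            kw[f"U_{gate}"] = _uniform(rng, (H, H), H)
            kw[f"b_{gate}"] = ad.parameter(np.zeros(H))
        return GruParams(**kw)

    return ModelParams(
        conv_layers=conv_layers,
        W_l=_uniform(rng, (flat_dim, conv_cfg.fc_out_dim), flat_dim),
        gru_fwd=gru(),
        gru_bwd=gru(),
        attention=AttentionParams(
            W_t=_uniform(rng, (2 * H, att), 2 * H),
            b_t=ad.parameter(np.zeros(att)),
            u_p=_uniform(rng, (att,), att),
        ),
        W_c=_uniform(rng, (conv_cfg.fc_out_dim, 2), conv_cfg.fc_out_dim),
        b_c=ad.parameter(np.zeros(2)),
        W_v=_uniform(rng, (2 * H, 2), 2 * H),
        b_v=ad.parameter(np.zeros(2)),
        input_shape=(n_drugs, n_diseases),
    )


def _softmax_np(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max()
    e = np.exp(shifted)
    return e / e.sum()


def pair_score(
    c_ij: np.ndarray,
    g_ij: np.ndarray | None,
    params: ModelParams,
    alpha1: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Head scores for one pair: (combined score, score_c, score_g).

    With no path representation the combined score is the CNN head alone.
    """
    score_c = _softmax_np(np.asarray(c_ij, float) @ params.W_c.value + params.b_c.value)
    if g_ij is None:
        return score_c, score_c, None
    score_g = _softmax_np(np.asarray(g_ij, float) @ params.W_v.value + params.b_v.value)
    return alpha1 * score_c + (1.0 - alpha1) * score_g, score_c, score_g


def combined_loss(
    score_c: np.ndarray,
    score_g: np.ndarray | None,
    y_real: int,
    alpha1: float,
) -> float:
    """alpha1-weighted sum of the two heads' binary cross-entropies.

    Log arguments are clipped at 1e-12.  A missing path head collapses the
    loss to the CNN head's cross-entropy at full weight.
    """
    if y_real not in (0, 1):
        raise ValueError("y_real must be 0 or 1")

    def ce(score: np.ndarray) -> float:
        p = np.clip(score, 1e-12, None)
        return float(-(y_real * np.log(p[ASSOCIATED]) + (1 - y_real) * np.log(p[1 - ASSOCIATED])))

    if score_g is None:
        return ce(np.asarray(score_c))
    return alpha1 * ce(np.asarray(score_c)) + (1.0 - alpha1) * ce(np.asarray(score_g))


def sample_training_pairs(
    net: HeteroNetwork,
    fold_positives: np.ndarray,
    neg_ratio: float = 1.0,
    seed: int = 0,
    forbidden: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Positives plus seeded uniformly sampled unknown pairs as negatives.

    Returns ``(pairs, labels)`` with pairs of shape (n, 2).  ``forbidden``
    optionally lists extra (i, j) pairs that must not be drawn (e.g. a
    held-out test set).
    """
    if neg_ratio <= 0:
        raise ValueError("neg_ratio must be positive")
    pos = np.asarray(fold_positives, dtype=int).reshape(-1, 2)
    unknown = np.argwhere(net.A == 0)
    if forbidden is not None and len(forbidden):
        forb = {(int(i), int(j)) for i, j in np.asarray(forbidden, dtype=int)}
        unknown = np.array(
            [p for p in unknown if (int(p[0]), int(p[1])) not in forb], dtype=int
        ).reshape(-1, 2)
    n_neg = int(np.ceil(neg_ratio * len(pos)))
    if n_neg > len(unknown):
        raise ValueError(
            f"cannot sample {n_neg} negatives from {len(unknown)} unknown pairs"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(len(unknown), size=n_neg, replace=False)
    pairs = np.vstack([pos, unknown[take]])
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(n_neg, int)])
    return pairs, labels


class Adam:
    """Adam optimizer over a named dict of parameter tensors."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.value) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.value) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def train(
    net: HeteroNetwork,
    cfg: TrainConfig,
    conv_cfg: ConvConfig | None = None,
    gru_cfg: GruConfig | None = None,
    **estimator_kwargs,
) -> ModelParams:
    """Train on all known associations of ``net`` plus sampled negatives.

    Thin wrapper over :class:`cgardp.estimator.CGARDPClassifier`; returns
    the fitted :class:`ModelParams` (the per-epoch loss history lives on
    the estimator as ``loss_history_`` and is also attached to the result
    as ``params.loss_history``).
    """
    from .estimator import CGARDPClassifier

    cfg.validate()
    conv_cfg = conv_cfg or ConvConfig()
    gru_cfg = gru_cfg or GruConfig()
    positives = np.argwhere(net.A == 1)
    if len(positives) == 0:
        raise ValueError("network has no known associations to train on")
    pairs, labels = sample_training_pairs(net, positives, cfg.neg_ratio, cfg.seed)
    kwargs = dict(
        alpha1=cfg.alpha1,
        dropout_rate=cfg.dropout_rate,
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        filter_height=conv_cfg.filter_height,
        filter_width=conv_cfg.filter_width,
        n_filters=conv_cfg.n_filters_per_layer,
        padding=conv_cfg.padding,
        pool_window=conv_cfg.pool_window,
        fc_out_dim=conv_cfg.fc_out_dim,
        hidden_dim=gru_cfg.hidden_dim,
        attention_dim=gru_cfg.attention_dim,
        random_state=cfg.seed,
    )
    kwargs.update(estimator_kwargs)  # explicit keyword overrides win
    clf = CGARDPClassifier(**kwargs)
    clf.fit(pairs, labels, network=net)
    params = clf.params_
    params.loss_history = list(clf.loss_history_)  # type: ignore[attr-defined]
    return params
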