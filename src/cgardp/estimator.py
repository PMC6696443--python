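"""Scikit-learn-style estimator for drug-disease association prediction.

:class:`CGARDPClassifier` is a binary classifier over (drug, disease)
index pairs of a fixed heterogeneous network.  ``X`` is an integer array
of shape (n_pairs, 2) holding (drug_index, disease_index); ``y`` is the
0/1 association label.  The network itself (similarities + associations)
is passed to :meth:`fit` as the ``network`` keyword and retained for
prediction, mirroring how kernel-matrix estimators retain their training
context.

The estimator follows the scikit-learn contract (``get_params`` /
``set_params``, fitted attributes with trailing underscores, idempotent
``fit``) without importing scikit-learn, so it composes with its
model-selection utilities via duck typing.
"""

from __future__ import annotations

import inspect
from collections import defaultdict

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Tensor
from .local_encoder import ConvConfig, local_forward_batch, plan_conv_stack
from .netio import HeteroNetwork
from .pair_features import pad
from .path_encoder import GruConfig, attend_t, gru_sequence_t
from .path_enum import DISEASE, DRUG, build_graph_edges, enumerate_paths
from .trainer import ASSOCIATED, Adam, ModelParams, init_model_params

__all__ = ["PairBatchBuilder", "CGARDPClassifier", "predict_candidates"]


class PairBatchBuilder:
    """Precomputed per-network feature/path context for batched forwards.

    Holds the stacked node-feature matrix ``NF`` (drug k at row k, disease
    l at row n_drugs + l, each row being the node's (Nr+Nd) feature
    vector), the thresholded edge sets, and a cache of enumerated paths
    (as index tuples into ``NF``) per pair.
    """

    def __init__(
        self,
        net: HeteroNetwork,
        padding: tuple[int, int] = (1, 10),
        mask_known: bool = True,
        sim_threshold: float = 0.5,
        path_max_len: int = 3,
        path_cap: int | None = 8,
        exclude_direct: bool = True,
    ):
        self.net = net
        self.padding = tuple(padding)
        self.mask_known = mask_known
        self.path_max_len = path_max_len
        self.path_cap = path_cap
        self.exclude_direct = exclude_direct
        self.NF = np.vstack(
            [np.hstack([net.R, net.A]), np.hstack([net.A.T, net.D])]
        )
        self.edges = build_graph_edges(net, sim_threshold)
        self._path_cache: dict[tuple[int, int], tuple[tuple[int, ...], ...]] = {}

    @property
    def padded_shape(self) -> tuple[int, int]:
        p_r, p_c = self.padding
        return (2 + 2 * p_r, self.NF.shape[1] + 2 * p_c)

    def padded_batch(self, pairs: np.ndarray) -> np.ndarray:
        """(B, 2, Nr+Nd) feature matrices, masked and zero-padded."""
        nr = self.net.n_drugs
        i, j = pairs[:, 0], pairs[:, 1]
        X = np.stack([self.NF[i], self.NF[nr + j]], axis=1)
        if self.mask_known:
            rows = np.where(self.net.A[i, j] == 1.0)[0]
            X[rows, 0, nr + j[rows]] = 0.0
            X[rows, 1, i[rows]] = 0.0
        p_r, p_c = self.padding
        B, _, F = X.shape
        out = np.zeros((B, 2 + 2 * p_r, F + 2 * p_c))
        out[:, p_r : p_r + 2, p_c : p_c + F] = X
        return out

    def path_indices(self, i: int, j: int) -> tuple[tuple[int, ...], ...]:
        """Enumerated paths for one pair as tuples of NF row indices."""
        key = (int(i), int(j))
        cached = self._path_cache.get(key)
        if cached is None:
            ps = enumerate_paths(
                self.edges,
                key[0],
                key[1],
                max_len=self.path_max_len,
                cap=self.path_cap,
                exclude_direct=self.exclude_direct,
            )
            nr = self.net.n_drugs
            cached = tuple(
                tuple(idx if layer == DRUG else nr + idx for layer, idx in p)
                for p in ps.paths
            )
            self._path_cache[key] = cached
        return cached


class CGARDPClassifier:
    """CNN + attention-BiGRU classifier over drug-disease pairs.

    Parameters mirror the model description: the CNN branch encodes the
    padded 2 x (Nr+Nd) pair feature matrix through ``n_filters`` stacked
    convolution/pool layers into a local representation; the path branch
    encodes up to ``path_cap`` similarity/association paths per pair with
    a bidirectional GRU and path-level attention.  Two softmax heads are
    mixed by ``alpha1`` (``alpha1=1`` is a CNN-only ablation).
    """

    def __init__(
        self,
        alpha1: float = 0.5,
        dropout_rate: float = 0.5,
        learning_rate: float = 1e-3,
        epochs: int = 100,
        batch_size: int = 32,
        filter_height: int = 3,
        filter_width: int = 20,
        n_filters: tuple[int, ...] = (16, 32),
        padding: tuple[int, int] = (1, 10),
        pool_window: tuple[int, int] = (2, 2),
        fc_out_dim: int = 32,
        hidden_dim: int = 32,
        attention_dim: int = 32,
        path_max_len: int = 3,
        path_cap: int | None = 8,
        sim_threshold: float = 0.5,
        exclude_direct: bool = True,
        mask_known: bool = True,
        random_state: int | None = None,
    ):
        self.alpha1 = alpha1
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.filter_height = filter_height
        self.filter_width = filter_width
        self.n_filters = n_filters
        self.padding = padding
        self.pool_window = pool_window
        self.fc_out_dim = fc_out_dim
        self.hidden_dim = hidden_dim
        self.attention_dim = attention_dim
        self.path_max_len = path_max_len
        self.path_cap = path_cap
        self.sim_threshold = sim_threshold
        self.exclude_direct = exclude_direct
        self.mask_known = mask_known
        self.random_state = random_state

    # ---- scikit-learn plumbing ------------------------------------------

    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [p for p in sig.parameters if p != "self"]

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params) -> "CGARDPClassifier":
        valid = set(self._param_names())
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for CGARDPClassifier")
            setattr(self, k, v)
        return self

    # ---- configuration helpers ------------------------------------------

    def _conv_cfg(self) -> ConvConfig:
        return ConvConfig(
            filter_height=self.filter_height,
            filter_width=self.filter_width,
            n_filters_per_layer=tuple(self.n_filters),
            padding=tuple(self.padding),
            pool_window=tuple(self.pool_window),
            fc_out_dim=self.fc_out_dim,
        )

    def _gru_cfg(self) -> GruConfig:
        return GruConfig(hidden_dim=self.hidden_dim, attention_dim=self.attention_dim)

    def _make_builder(self, net: HeteroNetwork) -> PairBatchBuilder:
        return PairBatchBuilder(
            net,
            padding=tuple(self.padding),
            mask_known=self.mask_known,
            sim_threshold=self.sim_threshold,
            path_max_len=self.path_max_len,
            path_cap=self.path_cap,
            exclude_direct=self.exclude_direct,
        )

    # ---- forward pass ----------------------------------------------------

    def _forward_batch(
        self,
        builder: PairBatchBuilder,
        params: ModelParams,
        pairs: np.ndarray,
        plans,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor | None, list[int]]:
        """Returns (score_c (B,2), score_g (Bp,2) or None, batch rows with paths)."""
        xp = builder.padded_batch(pairs)[:, None]
        B = xp.shape[0]
        drop_flat = None
        q = 1.0 - self.dropout_rate
        if rng is not None and self.dropout_rate > 0.0:
            flat_dim = params.W_l.value.shape[0]
            drop_flat = (rng.random((B, flat_dim)) < q) / q
        c = local_forward_batch(
            ad.constant(xp), params.conv_layers, params.W_l, self._conv_cfg(), plans,
            dropout_mask=drop_flat,
        )
        score_c = ad.softmax(c @ params.W_c + params.b_c, axis=-1)

        groups: dict[int, list[tuple[int, tuple[int, ...]]]] = defaultdict(list)
        for b in range(B):
            for p in builder.path_indices(pairs[b, 0], pairs[b, 1]):
                groups[len(p)].append((b, p))
        if not groups:
            return score_c, None, []
        chunks: list[Tensor] = []
        pair_of_path: list[int] = []
        for L in sorted(groups):
            entries = groups[L]
            idx = np.array([e[1] for e in entries], dtype=np.intp)
            feats = builder.NF[idx]  # (P, L, F)
            h_f = gru_sequence_t([feats[:, t] for t in range(L)], params.gru_fwd)
            h_b = gru_sequence_t(
                [feats[:, t] for t in range(L - 1, -1, -1)], params.gru_bwd
            )
            chunks.append(ad.concatenate([h_f, h_b], axis=1))
            pair_of_path.extend(e[0] for e in entries)
        H_all = chunks[0] if len(chunks) == 1 else ad.concatenate(chunks, axis=0)
        if rng is not None and self.dropout_rate > 0.0:
            mask = (rng.random(H_all.shape) < q) / q
            H_all = H_all * ad.constant(mask)
        rows_by_pair: dict[int, list[int]] = defaultdict(list)
        for row, b in enumerate(pair_of_path):
            rows_by_pair[b].append(row)
        with_paths = sorted(rows_by_pair)
        g_rows = [
            attend_t(H_all.take(rows_by_pair[b]), params.attention)[0]
            for b in with_paths
        ]
        G = g_rows[0] if len(g_rows) == 1 else ad.concatenate(g_rows, axis=0)
        score_g = ad.softmax(G @ params.W_v + params.b_v, axis=-1)
        return score_c, score_g, with_paths

    def _batch_loss(
        self,
        score_c: Tensor,
        score_g: Tensor | None,
        with_paths: list[int],
        y: np.ndarray,
    ) -> Tensor:
        B = len(y)
        Y = np.zeros((B, 2))
        Y[np.arange(B), np.where(y == 1, ASSOCIATED, 1 - ASSOCIATED)] = 1.0
        ce_c = -((ad.clipped_log(score_c) * ad.constant(Y)).sum(axis=1))
        w1 = np.full(B, 1.0)
        w1[with_paths] = self.alpha1
        total = (ce_c * ad.constant(w1)).sum()
        if score_g is not None:
            ce_g = -((ad.clipped_log(score_g) * ad.constant(Y[with_paths])).sum(axis=1))
            total = total + ce_g.sum() * (1.0 - self.alpha1)
        return total * (1.0 / B)

    def _combined_prob(
        self, score_c: Tensor, score_g: Tensor | None, with_paths: list[int]
    ) -> np.ndarray:
        p = score_c.value[:, ASSOCIATED].copy()
        if score_g is not None:
            pg = score_g.value[:, ASSOCIATED]
            for row, b in enumerate(with_paths):
                p[b] = self.alpha1 * p[b] + (1.0 - self.alpha1) * pg[row]
        return p

    # ---- estimator API ---------------------------------------------------

    def fit(
        self, X: np.ndarray, y: np.ndarray, network: HeteroNetwork | None = None
    ) -> "CGARDPClassifier":
        if network is None:
            raise ValueError("fit requires the heterogeneous network (network=...)")
        pairs = np.asarray(X, dtype=int)
        y = np.asarray(y, dtype=int)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("X must have shape (n_pairs, 2)")
        if len(pairs) != len(y):
            raise ValueError("X and y length mismatch")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary")
        if pairs[:, 0].min(initial=0) < 0 or pairs[:, 0].max(initial=0) >= network.n_drugs:
            raise IndexError("drug index out of range")
        if pairs[:, 1].min(initial=0) < 0 or pairs[:, 1].max(initial=0) >= network.n_diseases:
            raise IndexError("disease index out of range")
        conv_cfg, gru_cfg = self._conv_cfg(), self._gru_cfg()
        rng = np.random.default_rng(self.random_state)
        builder = self._make_builder(network)
        plans, _ = plan_conv_stack(conv_cfg, builder.padded_shape)
        params = init_model_params(
            network.n_drugs, network.n_diseases, conv_cfg, gru_cfg, rng
        )
        opt = Adam(params.named_tensors(), lr=self.learning_rate)
        history: list[float] = []
        n = len(pairs)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                opt.zero_grad()
                score_c, score_g, with_paths = self._forward_batch(
                    builder, params, pairs[sel], plans, rng=rng
                )
                loss = self._batch_loss(score_c, score_g, with_paths, y[sel])
                if not np.isfinite(loss.value):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch start {start}"
                    )
                loss.backward()
                opt.step()
                epoch_loss += float(loss.value) * len(sel)
            history.append(epoch_loss / n)
        params.check_finite()
        self.network_ = network
        self.builder_ = builder
        self.plans_ = plans
        self.params_ = params
        self.loss_history_ = history
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    @classmethod
    def from_params(
        cls, params: ModelParams, network: HeteroNetwork, **kwargs
    ) -> "CGARDPClassifier":
        """Wrap pre-trained parameters (e.g. a loaded checkpoint)."""
        if params.input_shape != (network.n_drugs, network.n_diseases):
            raise ValueError(
                f"model trained on network of shape {params.input_shape}, "
                f"got ({network.n_drugs}, {network.n_diseases})"
            )
        clf = cls(**kwargs)
        clf.network_ = network
        clf.builder_ = clf._make_builder(network)
        clf.plans_, _ = plan_conv_stack(clf._conv_cfg(), clf.builder_.padded_shape)
        clf.params_ = params
        clf.loss_history_ = getattr(params, "loss_history", [])
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = 2
        return clf

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """P(not associated), P(associated) per pair (dropout disabled)."""
        self._check_fitted()
        pairs = np.asarray(X, dtype=int).reshape(-1, 2)
        out = np.empty(len(pairs))
        for start in range(0, len(pairs), batch_size):
            chunk = pairs[start : start + batch_size]
            score_c, score_g, with_paths = self._forward_batch(
                self.builder_, self.params_, chunk, self.plans_, rng=None
            )
            out[start : start + len(chunk)] = self._combined_prob(
                score_c, score_g, with_paths
            )
        return np.column_stack([1.0 - out, out])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def predict_candidates(
    clf: CGARDPClassifier, drugs: list[str] | None = None
) -> pd.DataFrame:
    """Ranked unknown-pair candidates for the requested drugs (or all).

    Known associations are excluded; rows are sorted per drug by
    descending score with ties broken by disease id for reproducibility.
    """
    clf._check_fitted()
    net = clf.network_
    if drugs is None:
        drug_idx = list(range(net.n_drugs))
    else:
        lookup = {d: k for k, d in enumerate(net.drug_ids)}
        missing = [d for d in drugs if d not in lookup]
        if missing:
            raise KeyError(f"unknown drug ids: {missing}")
        drug_idx = [lookup[d] for d in drugs]
    rows = []
    for i in drug_idx:
        unknown = np.where(net.A[i] == 0)[0]
        if len(unknown) == 0:
            continue
        pairs = np.column_stack([np.full(len(unknown), i), unknown])
        scores = clf.predict_proba(pairs)[:, 1]
        for j, s in zip(unknown, scores):
            rows.append((net.drug_ids[i], net.disease_ids[j], float(s)))
    df = pd.DataFrame(rows, columns=["drug", "disease", "score"])
    if len(df):
        df = df.sort_values(
            ["drug", "score", "disease"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return df
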