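"""Training loop, masked loss, estimator interface and ablation harness.

Unlabeled residues and padded positions carry no gradient and no metric
weight anywhere in this module. Training is plain Adam over minibatches of
padded protein batches, seeded end to end; the parameters with the best
validation AUC are retained.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._autodiff import Adam, Tensor
from .io import DISORDERED, UNLABELED, make_cv_folds
from .metrics import MetricsReport, evaluate_scores, roc_auc
from .network import FusionNetwork, ModelConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "masked_loss",
    "pad_batch",
    "train",
    "evaluate",
    "DisorderClassifier",
    "run_ablation",
    "paired_fusion_comparison",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 3e-3
    class_weighting: bool = False
    patience: int | None = None   # early stopping on validation AUC
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


def masked_loss(logits: Tensor, labels: np.ndarray,
                class_weights: np.ndarray | None = None) -> Tensor:
    """Mean two-class cross-entropy over labeled residues only.

    ``labels`` is (B, L) over {ORDERED, DISORDERED, UNLABELED}; unlabeled and
    padded positions (marked UNLABELED) contribute exactly zero. Optional
    ``class_weights`` is a length-2 vector [w_ordered, w_disordered].
    """
    labels = np.asarray(labels)
    labeled = labels != UNLABELED
    n = int(labeled.sum())
    if n == 0:
        raise ValueError("batch contains no labeled residues")
    onehot = np.zeros(labels.shape + (2,))
    onehot[..., 1] = (labels == DISORDERED) & labeled
    onehot[..., 0] = (labels != DISORDERED) & labeled
    weight = np.ones(labels.shape)
    if class_weights is not None:
        weight = np.where(labels == DISORDERED, class_weights[1],
                          class_weights[0])
    weight = weight * labeled
    logp = logits.log_softmax(axis=-1)
    total = (logp * (onehot * weight[..., None])).sum()
    return -total * (1.0 / weight.sum())


def _inverse_frequency_weights(labels: np.ndarray) -> np.ndarray | None:
    labeled = labels[labels != UNLABELED]
    n_pos = int((labeled == DISORDERED).sum())
    n_neg = len(labeled) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    n = len(labeled)
    return np.array([n / (2.0 * n_neg), n / (2.0 * n_pos)])


def pad_batch(
    R_b: Sequence[np.ndarray], R_p: Sequence[np.ndarray],
    labels: Sequence[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Zero-pad a list of per-protein arrays into (B, L, .) batch arrays.

    Returns (R_b, R_p, mask, labels); padded label positions are UNLABELED.
    """
    B = len(R_b)
    L = max(m.shape[0] for m in R_b)
    out_b = np.zeros((B, L, R_b[0].shape[1]))
    out_p = np.zeros((B, L, R_p[0].shape[1]))
    mask = np.zeros((B, L), dtype=bool)
    out_y = None if labels is None else np.full((B, L), UNLABELED, dtype=np.int8)
    for i, (mb, mp) in enumerate(zip(R_b, R_p)):
        n = mb.shape[0]
        out_b[i, :n] = mb
        out_p[i, :n] = mp
        mask[i, :n] = True
        if labels is not None:
            out_y[i, :n] = labels[i]
    return out_b, out_p, mask, out_y


def _predict_batched(net: FusionNetwork, R_b, R_p,
                     batch_size: int = 64) -> list[np.ndarray]:
    scores = []
    for a in range(0, len(R_b), batch_size):
        bb, bp, mask, _ = pad_batch(R_b[a:a + batch_size], R_p[a:a + batch_size])
        s = net.predict_scores(bb, bp, mask)
        for i, m in enumerate(R_b[a:a + batch_size]):
            scores.append(s[i, :m.shape[0]])
    return scores


def train(
    config: ModelConfig,
    train_data: tuple[Sequence[np.ndarray], Sequence[np.ndarray], Sequence[np.ndarray]],
    val_data: tuple[Sequence[np.ndarray], Sequence[np.ndarray], Sequence[np.ndarray]],
    train_config: TrainConfig,
) -> tuple[FusionNetwork, pd.DataFrame]:
    """Train a :class:`FusionNetwork`, retaining the best-validation-AUC state.

    ``train_data``/``val_data`` are (R_b list, R_p list, labels list)
    triples. Returns the network (restored to its best state) and a per-epoch
    history frame with columns epoch, train_loss, val_auc.
    """
    Rb_tr, Rp_tr, y_tr = train_data
    Rb_va, Rp_va, y_va = val_data
    net = FusionNetwork(config)
    params = net.parameters()
    opt = Adam(params, lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    n = len(Rb_tr)
    history = []
    best_auc, best_state, since_best = -np.inf, None, 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        losses = []
        for a in range(0, n, train_config.batch_size):
            idx = order[a:a + train_config.batch_size]
            bb, bp, mask, by = pad_batch(
                [Rb_tr[i] for i in idx], [Rp_tr[i] for i in idx],
                [y_tr[i] for i in idx])
            weights = (_inverse_frequency_weights(by)
                       if train_config.class_weighting else None)
            logits = net.forward(bb, bp, mask, train=True, rng=rng)
            loss = masked_loss(logits, by, weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_scores = _predict_batched(net, Rb_va, Rp_va)
        val_auc = roc_auc(np.concatenate(val_scores), np.concatenate(y_va))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_auc": val_auc})
        logger.info("epoch %d: loss %.4f, val AUC %.4f", epoch,
                    history[-1]["train_loss"], val_auc)
        if val_auc > best_auc:
            best_auc, since_best = val_auc, 0
            best_state = [p.data.copy() for p in params]
        else:
            since_best += 1
            if (train_config.patience is not None
                    and since_best > train_config.patience):
                break
    if best_state is not None:
        for p, s in zip(params, best_state):
            p.data = s
    return net, pd.DataFrame(history)


def evaluate(net: FusionNetwork,
             data: tuple[Sequence[np.ndarray], Sequence[np.ndarray], Sequence[np.ndarray]],
             threshold: float | None = None,
             per_protein_average: bool = False) -> MetricsReport:
    """Score a dataset with the network and compute the pooled metric suite."""
    Rb, Rp, y = data
    scores = _predict_batched(net, Rb, Rp)
    thr = net.config.threshold if threshold is None else threshold
    return evaluate_scores(scores, y, threshold=thr,
                           per_protein_average=per_protein_average)


class DisorderClassifier(BaseEstimator):
    """Residue-level disorder classifier with a scikit-learn surface.

    ``X`` is a list of per-protein ``(R_b, R_p)`` feature-matrix pairs and
    ``y`` a list of per-residue label vectors over {0 = ordered,
    1 = disordered, -1 = unlabeled}. After ``fit`` the trained network is in
    ``network_`` and the per-epoch history in ``history_``. ``predict_proba``
    returns one (L, 2) array per protein; ``predict`` binary calls at the
    configured threshold.
    """

    def __init__(self, d_h: int = 64, d_model: int = 64, n_layers: int = 2,
                 n_heads: int = 4, d_ff: int | None = None,
                 dropout: float = 0.1, bidirectional: bool = False,
                 positional_encoding: bool = False,
                 fusion_mode: str = "fusioncell",
                 additive_memory: bool = False, threshold: float = 0.5,
                 epochs: int = 20, batch_size: int = 32,
                 learning_rate: float = 3e-3, class_weighting: bool = False,
                 patience: int | None = None, validation_fraction: float = 0.2,
                 seed: int = 0):
        self.d_h = d_h
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.dropout = dropout
        self.bidirectional = bidirectional
        self.positional_encoding = positional_encoding
        self.fusion_mode = fusion_mode
        self.additive_memory = additive_memory
        self.threshold = threshold
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.class_weighting = class_weighting
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _model_config(self, d_b: int, d_p: int) -> ModelConfig:
        return ModelConfig(
            d_b=d_b, d_p=d_p, d_h=self.d_h, d_model=self.d_model,
            n_layers=self.n_layers, n_heads=self.n_heads, d_ff=self.d_ff,
            dropout=self.dropout, bidirectional=self.bidirectional,
            positional_encoding=self.positional_encoding,
            fusion_mode=self.fusion_mode,
            additive_memory=self.additive_memory,
            threshold=self.threshold, seed=self.seed,
        )

    def fit(self, X, y, validation_data=None):
        Rb = [np.asarray(p[0], dtype=float) for p in X]
        Rp = [np.asarray(p[1], dtype=float) for p in X]
        y = [np.asarray(v) for v in y]
        if validation_data is not None:
            Xv, yv = validation_data
            val = ([np.asarray(p[0], dtype=float) for p in Xv],
                   [np.asarray(p[1], dtype=float) for p in Xv],
                   [np.asarray(v) for v in yv])
            tr = (Rb, Rp, y)
        else:
            k = max(2, int(round(1.0 / max(self.validation_fraction, 1e-9))))
            folds = make_cv_folds([str(i) for i in range(len(Rb))], k=k,
                                  seed=self.seed)
            va_idx = [i for i in range(len(Rb))
                      if folds.fold_of[str(i)] == 0]
            tr_idx = [i for i in range(len(Rb))
                      if folds.fold_of[str(i)] != 0]
            tr = ([Rb[i] for i in tr_idx], [Rp[i] for i in tr_idx],
                  [y[i] for i in tr_idx])
            val = ([Rb[i] for i in va_idx], [Rp[i] for i in va_idx],
                   [y[i] for i in va_idx])
        config = self._model_config(Rb[0].shape[1], Rp[0].shape[1])
        tc = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                         learning_rate=self.learning_rate,
                         class_weighting=self.class_weighting,
                         patience=self.patience, seed=self.seed)
        self.network_, history = train(config, tr, val, tc)
        self.history_ = history
        self.config_ = config
        self.classes_ = np.array([0, 1])
        self.n_features_b_ = Rb[0].shape[1]
        self.n_features_p_ = Rp[0].shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")

    def predict_scores(self, X) -> list[np.ndarray]:
        """Per-protein disordered-class probability vectors."""
        self._check_fitted()
        Rb = [np.asarray(p[0], dtype=float) for p in X]
        Rp = [np.asarray(p[1], dtype=float) for p in X]
        return _predict_batched(self.network_, Rb, Rp)

    def predict_proba(self, X) -> list[np.ndarray]:
        return [np.column_stack([1.0 - s, s]) for s in self.predict_scores(X)]

    def predict(self, X) -> list[np.ndarray]:
        return [(s >= self.threshold).astype(np.int8)
                for s in self.predict_scores(X)]

    def score(self, X, y) -> float:
        """Pooled residue-level AUC over labeled residues."""
        scores = self.predict_scores(X)
        return roc_auc(np.concatenate(scores),
                       np.concatenate([np.asarray(v) for v in y]))


def _drop_spans(matrices: Sequence[np.ndarray],
                spans: Mapping[str, tuple[int, int]],
                dropped: Sequence[str]) -> list[np.ndarray]:
    keep_cols = np.ones(matrices[0].shape[1], dtype=bool)
    for name in dropped:
        a, b = spans[name]
        keep_cols[a:b] = False
    return [m[:, keep_cols] for m in matrices]


def run_ablation(
    X, y,
    base_params: Mapping,
    variants: Sequence[Mapping],
    b_spans: Mapping[str, tuple[int, int]] | None = None,
    p_spans: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Train and evaluate feature-group / fusion-mode variants.

    Each variant is a mapping with a ``name``, optional estimator parameter
    overrides (e.g. ``fusion_mode``), and optional ``drop_b`` / ``drop_p``
    lists naming column spans (from ``b_spans`` / ``p_spans``) to remove from
    the traditional / PLM stream. All variants share the estimator seed and
    internal validation fold, so rows are directly comparable. Returns one
    tidy row per variant with the validation metric suite.
    """
    rows = []
    for variant in variants:
        variant = dict(variant)
        name = variant.pop("name")
        drop_b = variant.pop("drop_b", [])
        drop_p = variant.pop("drop_p", [])
        Rb = [np.asarray(p[0], dtype=float) for p in X]
        Rp = [np.asarray(p[1], dtype=float) for p in X]
        if drop_b:
            if b_spans is None:
                raise ValueError("drop_b requires b_spans")
            Rb = _drop_spans(Rb, b_spans, drop_b)
        if drop_p:
            if p_spans is None:
                raise ValueError("drop_p requires p_spans")
            Rp = _drop_spans(Rp, p_spans, drop_p)
        if Rb[0].shape[1] == 0 or Rp[0].shape[1] == 0:
            raise ValueError(f"variant {name!r} disables an entire stream")
        est = DisorderClassifier(**{**base_params, **variant})
        est.fit(list(zip(Rb, Rp)), y)
        # evaluate on the estimator's internal validation fold
        folds = make_cv_folds([str(i) for i in range(len(Rb))],
                              k=max(2, int(round(1.0 / est.validation_fraction))),
                              seed=est.seed)
        va = [i for i in range(len(Rb)) if folds.fold_of[str(i)] == 0]
        report = evaluate(est.network_,
                          ([Rb[i] for i in va], [Rp[i] for i in va],
                           [np.asarray(y[i]) for i in va]))
        row = {"variant": name, "d_b": Rb[0].shape[1], "d_p": Rp[0].shape[1],
               **report.to_dict()}
        rows.append(row)
    return pd.DataFrame(rows)


def paired_fusion_comparison(
    sim_params,
    model_params: Mapping | None = None,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> pd.DataFrame:
    """Fusion-cell vs concatenation-LSTM under paired seeds.

    For each seed a fresh synthetic dataset is generated; both fusion modes
    are trained with identical folds, initial-seed and shuffling, and scored
    on the validation fold. Also reports the Bayes-oracle AUC on the same
    validation residues — the ceiling for both. Returns one row per seed.
    """
    from dataclasses import replace as _replace

    from .simulate import bayes_scores, simulate_dataset

    model_params = dict(model_params or {})
    rows = []
    for seed in seeds:
        ds = simulate_dataset(_replace(sim_params, seed=int(seed)))
        X = list(zip(ds.R_b, ds.R_p))
        y = ds.labels
        aucs = {}
        for mode in ("fusioncell", "concat_lstm"):
            est = DisorderClassifier(fusion_mode=mode, seed=int(seed),
                                     **model_params)
            est.fit(X, y)
            aucs[mode] = float(est.history_["val_auc"].max())
        folds = make_cv_folds([str(i) for i in range(len(X))], k=5,
                              seed=int(seed))
        va = [i for i in range(len(X)) if folds.fold_of[str(i)] == 0]
        oracle = bayes_scores(ds)
        bayes_auc = roc_auc(
            np.concatenate([oracle[i] for i in va]),
            np.concatenate([y[i] for i in va]))
        rows.append({"seed": int(seed),
                     "auc_fusioncell": aucs["fusioncell"],
                     "auc_concat_lstm": aucs["concat_lstm"],
                     "auc_bayes_oracle": bayes_auc})
    return pd.DataFrame(rows)
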