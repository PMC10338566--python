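"""Sequence classifier: frozen CNN features → FC → stateless LSTM → head.

The architecture mirrors the transfer-learning design used for
out-of-body detection in laparoscopic video: a feature extractor
pretrained (or fixed) ahead of time and never updated, a dropout +
linear layer in place of the original classifier head, a stateless LSTM
that integrates evidence over a 32-frame sequence (classes persist for
seconds, so temporal context disambiguates single odd frames), and a
final dropout-50% + linear layer with 2 or 5 outputs.  Because the
hidden state is reset for every sequence, the output for a sequence
never depends on previously processed sequences.

Class imbalance (inside frames outnumber outside ~5:1, and the rare
outside sub-classes are far smaller) is handled by focal loss: a
cross-entropy whose modulating factor ``(1 - p_true)^gamma`` decays to
zero for confidently correct frames, concentrating the gradient on
hard, rare examples.

:class:`InsideOutsideSequenceClassifier` follows the scikit-learn
estimator contract (``fit`` / ``predict`` / ``predict_proba``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes)
so it composes with sklearn model selection; the module-level
:func:`forward`, :func:`focal_loss` and :func:`predict_labels` are the
functional surface over the same code.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ioda import nn
from ioda.annotation import BinaryClass, FrameClass, to_binary

_EPS = 1e-12  # probability clamp: loss is finite even at p_true == 0

BACKBONES = {
    "tiny_conv": nn.TINY_CONV_FEATURE_DIM,
    "alexnet_pretrained": nn.ALEXNET_FEATURE_DIM,
}

#: Head widths per backbone: the full-scale configuration keeps the
#: classic FC6 width; the desk-scale backbone uses a narrow head.
_DEFAULT_FC_WIDTH = {"alexnet_pretrained": 4096, "tiny_conv": 256}
_DEFAULT_HIDDEN = {"alexnet_pretrained": 512, "tiny_conv": 64}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; backbone weights are never trainable."""

    backbone: Literal["tiny_conv", "alexnet_pretrained"] = "tiny_conv"
    feature_dim: int = nn.TINY_CONV_FEATURE_DIM
    fc_width: int = 4096
    recurrent_hidden: int = 512
    head_dropout: float = 0.5
    input_dropout: float = 0.5
    num_classes: int = 2
    trainable_set: tuple[str, ...] = ("fc", "recurrent", "head")

    def __post_init__(self) -> None:
        if self.num_classes not in (2, 5):
            raise ValueError(f"num_classes must be 2 or 5, got {self.num_classes}")
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        bad = set(self.trainable_set) - {"fc", "recurrent", "head"}
        if bad:
            raise ValueError(
                f"trainable_set may only contain fc/recurrent/head, got {sorted(bad)}"
            )


@dataclass(frozen=True)
class FocalLossParams:
    """gamma=0 with unit alpha reduces focal loss exactly to cross-entropy."""

    gamma: float = 2.0
    alpha: tuple[float, ...] | None = None  # None → unit weight per class

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.alpha is not None and any(a < 0 for a in self.alpha):
            raise ValueError("alpha components must be >= 0")


def class_vocabulary(num_classes: int) -> list[str]:
    """Ordered class tokens for the binary or five-way task."""
    if num_classes == 2:
        return [c.value for c in BinaryClass]
    if num_classes == 5:
        return [c.value for c in FrameClass]
    raise ValueError(f"num_classes must be 2 or 5, got {num_classes}")


def outside_indices(vocabulary: Sequence[str]) -> list[int]:
    """Indices of OUTSIDE-mapped classes in a vocabulary (fail-closed set)."""
    out = []
    for i, token in enumerate(vocabulary):
        if token in BinaryClass.__members__ and BinaryClass(token) is BinaryClass.OUTSIDE:
            out.append(i)
        elif token in FrameClass.__members__ and to_binary(FrameClass(token)) is BinaryClass.OUTSIDE:
            out.append(i)
    return out


# -- focal loss -------------------------------------------------------------------


def focal_loss(
    probabilities: np.ndarray,
    targets: np.ndarray,
    params: FocalLossParams = FocalLossParams(),
) -> float:
    """Mean over frames of ``-alpha[y] * (1 - p_y)^gamma * log(p_y)``.

    ``probabilities`` has one row of class probabilities per frame;
    ``targets`` are integer class indices.  ``p_y = 0`` is clamped to a
    small epsilon, so the loss is always finite.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    targets = np.asarray(targets, dtype=int)
    p = np.clip(probabilities[np.arange(len(targets)), targets], _EPS, 1.0)
    alpha = 1.0 if params.alpha is None else np.asarray(params.alpha)[targets]
    if params.gamma == 0:
        mod = 1.0
    else:
        mod = (1.0 - p) ** params.gamma
    return float(np.mean(-alpha * mod * np.log(p)))


def focal_loss_grad(
    logits: np.ndarray, targets: np.ndarray, params: FocalLossParams
) -> tuple[float, np.ndarray]:
    """(mean focal loss, gradient w.r.t. logits) for softmax outputs.

    Row ``n``'s gradient is ``dL/dp_y * p_y * (delta_{jy} - p_j) / N``
    with ``dL/dp = -alpha * [ (1-p)^g / p - g (1-p)^{g-1} log p ]``.
    """
    probs = nn.softmax(logits)
    flat = probs.reshape(-1, probs.shape[-1])
    t = np.asarray(targets).reshape(-1)
    n = len(t)
    idx = np.arange(n)
    p = np.clip(flat[idx, t], _EPS, 1.0 - _EPS)
    alpha = np.ones(n) if params.alpha is None else np.asarray(params.alpha, dtype=float)[t]
    g = params.gamma
    one_minus = 1.0 - p
    if g == 0:
        mod = np.ones(n)
        dmod = np.zeros(n)
    else:
        mod = one_minus**g
        dmod = -g * one_minus ** (g - 1)
    loss = float(np.mean(-alpha * mod * np.log(p)))
    dL_dp = -alpha * (dmod * np.log(p) + mod / p)
    dflat = (dL_dp * p)[:, None] * (-flat)
    dflat[idx, t] += dL_dp * p
    return loss, (dflat / n).reshape(logits.shape)


# -- functional ops over a fitted model -------------------------------------------


def forward(model: "InsideOutsideSequenceClassifier", sequence: np.ndarray):
    """Score one sequence of L preprocessed frames → (L×C scores, L×C probs)."""
    check_is_fitted(model, "weights_")
    seq = np.asarray(sequence)
    if seq.ndim == 2:  # already backbone features (L, F)
        feats = seq[None]
    elif seq.ndim == 4:
        if seq.shape[1:3] != (224, 224) or seq.shape[3] != 3:
            raise ValueError(f"expected (L, 224, 224, 3) frames, got {seq.shape}")
        feats = model.extract_features(seq)[None]
    else:
        raise ValueError(f"expected (L, 224, 224, 3) or (L, feature_dim), got {seq.shape}")
    logits = model._forward(feats, training=False, rng=None)[0]
    return logits[0], nn.softmax(logits[0])


def predict_labels(
    scores: np.ndarray, pad_count: int = 0, vocabulary: Sequence[str] | None = None
) -> list[str]:
    """Row-wise argmax with the fail-closed tie rule; padded rows dropped.

    An exact tie between classes is resolved toward the OUTSIDE-mapped
    class with the lowest index (censoring a frame is recoverable; leaking
    one is not); a tie among inside classes only falls back to the lowest
    index.
    """
    scores = np.asarray(scores)
    if not 0 <= pad_count < len(scores):
        raise ValueError(f"pad_count {pad_count} must be < L={len(scores)}")
    vocab = list(vocabulary) if vocabulary is not None else class_vocabulary(scores.shape[1])
    outside = set(outside_indices(vocab))
    labels = []
    for row in scores[: len(scores) - pad_count]:
        top = np.flatnonzero(row == row.max())
        tied_outside = [i for i in top if i in outside]
        labels.append(vocab[tied_outside[0] if tied_outside else top[0]])
    return labels


# -- the estimator ----------------------------------------------------------------


class InsideOutsideSequenceClassifier(ClassifierMixin, BaseEstimator):
    """Frozen-backbone CNN-LSTM frame-sequence classifier.

    Parameters
    ----------
    backbone:
        ``"tiny_conv"`` — a small frozen He-initialized conv net (64
        features) for CPU-scale work; ``"alexnet_pretrained"`` — AlexNet
        feature layers (9216 features) loaded from ``backbone_weights_path``.
        Backbone parameters are never trained.
    num_classes:
        2 (inside/outside) or 5 (full taxonomy).
    fc_width, recurrent_hidden:
        Widths of the trainable linear layer and LSTM; ``None`` picks the
        backbone's preset (4096/512 for alexnet, 256/64 for tiny_conv).
    trainable:
        Subset of ``{"fc", "recurrent", "head"}`` updated during training;
        the strict transfer-learning mode is ``("head",)``.
    gamma, alpha:
        Focal-loss parameters. ``alpha="balanced"`` uses inverse class
        frequency normalized to mean 1; a class absent from the training
        labels gets weight 0 (with a warning).
    epochs, learning_rate, beta1, beta2, epsilon, batch_size:
        Adam training-loop parameters; one epoch is one full pass over
        the training sequences.
    random_state:
        Governs initialization, shuffling and dropout; two runs with the
        same seed and data produce bit-identical weights.
    mixed_precision:
        Accepted for API compatibility; a no-op on CPU.

    Attributes
    ----------
    classes_ : ndarray of class tokens (vocabulary order, not sorted).
    weights_ : dict of trainable parameter arrays.
    backbone_weights_ : dict of frozen backbone arrays.
    config_ : resolved :class:`ModelConfig`.
    loss_log_ : list of per-epoch mean training losses.
    """

    def __init__(
        self,
        backbone: str = "tiny_conv",
        num_classes: int = 2,
        fc_width: int | None = None,
        recurrent_hidden: int | None = None,
        head_dropout: float = 0.5,
        input_dropout: float = 0.5,
        trainable: tuple[str, ...] = ("fc", "recurrent", "head"),
        gamma: float = 2.0,
        alpha="balanced",
        epochs: int = 5,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-8,
        batch_size: int = 8,
        random_state: int = 0,
        backbone_weights_path: str | None = None,
        mixed_precision: bool = False,
    ) -> None:
        self.backbone = backbone
        self.num_classes = num_classes
        self.fc_width = fc_width
        self.recurrent_hidden = recurrent_hidden
        self.head_dropout = head_dropout
        self.input_dropout = input_dropout
        self.trainable = trainable
        self.gamma = gamma
        self.alpha = alpha
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.batch_size = batch_size
        self.random_state = random_state
        self.backbone_weights_path = backbone_weights_path
        self.mixed_precision = mixed_precision

    # -- configuration -----------------------------------------------------------

    def _resolve_config(self) -> ModelConfig:
        return ModelConfig(
            backbone=self.backbone,
            feature_dim=BACKBONES[self.backbone],
            fc_width=self.fc_width or _DEFAULT_FC_WIDTH[self.backbone],
            recurrent_hidden=self.recurrent_hidden or _DEFAULT_HIDDEN[self.backbone],
            head_dropout=self.head_dropout,
            input_dropout=self.input_dropout,
            num_classes=self.num_classes,
            trainable_set=tuple(self.trainable),
        )

    def _load_backbone(self) -> dict[str, np.ndarray]:
        if self.backbone == "tiny_conv":
            return nn.tiny_conv_weights()
        if self.backbone_weights_path is None:
            raise ValueError(
                "backbone 'alexnet_pretrained' needs backbone_weights_path "
                "(an .npz of the pretrained feature-layer weights)"
            )
        return nn.load_alexnet_weights(self.backbone_weights_path)

    def extract_features(self, frames: np.ndarray, chunk: int = 32) -> np.ndarray:
        """Frozen-backbone features for (N, 224, 224, 3) preprocessed frames."""
        if not hasattr(self, "backbone_weights_"):
            self.backbone_weights_ = self._load_backbone()
        fwd = nn.tiny_conv_forward if self.backbone == "tiny_conv" else nn.alexnet_forward
        frames = np.asarray(frames, dtype=np.float32)
        parts = [
            fwd(frames[i : i + chunk], self.backbone_weights_)
            for i in range(0, len(frames), chunk)
        ]
        return np.concatenate(parts).astype(np.float64)

    # -- core forward/backward ----------------------------------------------------

    def _init_weights(self, cfg: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
        F, W, H, C = cfg.feature_dim, cfg.fc_width, cfg.recurrent_hidden, cfg.num_classes
        return {
            "fc.W": rng.standard_normal((F, W)) * np.sqrt(2.0 / F),
            "fc.b": np.zeros(W),
            "lstm.Wx": rng.standard_normal((W, 4 * H)) * np.sqrt(1.0 / W),
            "lstm.Wh": rng.standard_normal((H, 4 * H)) * np.sqrt(1.0 / H),
            "lstm.b": np.zeros(4 * H),
            "head.W": rng.standard_normal((H, C)) * np.sqrt(1.0 / H),
            "head.b": np.zeros(C),
        }

    def _forward(self, feats: np.ndarray, training: bool, rng):
        """feats (B, L, F) → logits (B, L, C); caches returned when training."""
        w = self.weights_
        cfg = self.config_
        h0, m0 = nn.dropout_forward(feats, cfg.input_dropout, rng, training)
        z1, fc_cache = nn.linear_forward(h0, w["fc.W"], w["fc.b"])
        a1 = nn.relu(z1)
        hs, lstm_cache = nn.lstm_forward(a1, w["lstm.Wx"], w["lstm.Wh"], w["lstm.b"])
        h2, m2 = nn.dropout_forward(hs, cfg.head_dropout, rng, training)
        logits, head_cache = nn.linear_forward(h2, w["head.W"], w["head.b"])
        if not training:
            return logits, None
        return logits, (m0, fc_cache, z1, lstm_cache, m2, head_cache)

    def _backward(self, dlogits: np.ndarray, caches) -> dict[str, np.ndarray]:
        w = self.weights_
        m0, fc_cache, z1, lstm_cache, m2, head_cache = caches
        dh2, dWhead, dbhead = nn.linear_backward(dlogits, head_cache, w["head.W"])
        dhs = nn.dropout_backward(dh2, m2)
        da1, dWx, dWh, dblstm = nn.lstm_backward(dhs, lstm_cache, w["lstm.Wx"], w["lstm.Wh"])
        dz1 = da1 * (z1 > 0)
        _, dWfc, dbfc = nn.linear_backward(dz1, fc_cache, w["fc.W"])
        grads = {
            "fc.W": dWfc,
            "fc.b": dbfc,
            "lstm.Wx": dWx,
            "lstm.Wh": dWh,
            "lstm.b": dblstm,
            "head.W": dWhead,
            "head.b": dbhead,
        }
        prefix = {"fc": "fc.", "recurrent": "lstm.", "head": "head."}
        keep = tuple(prefix[t] for t in self.config_.trainable_set)
        return {k: v for k, v in grads.items() if k.startswith(keep)}

    # -- sklearn API ---------------------------------------------------------------

    def _coerce_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 5:
            n, L = X.shape[:2]
            feats = self.extract_features(X.reshape(n * L, *X.shape[2:]))
            return feats.reshape(n, L, -1)
        if X.ndim == 3:
            if X.shape[-1] != BACKBONES[self.backbone]:
                raise ValueError(
                    f"feature dim {X.shape[-1]} does not match backbone "
                    f"{self.backbone!r} ({BACKBONES[self.backbone]})"
                )
            return X.astype(np.float64)
        raise ValueError(
            "X must be (n, L, 224, 224, 3) preprocessed frames or "
            f"(n, L, feature_dim) backbone features; got shape {X.shape}"
        )

    def _encode_y(self, y: np.ndarray, vocab: list[str]) -> np.ndarray:
        y = np.asarray(y)
        if np.issubdtype(y.dtype, np.integer):
            if y.min() < 0 or y.max() >= len(vocab):
                raise ValueError("y indices out of vocabulary range")
            return y.astype(int)
        # FrameClass/BinaryClass are str enums, so they hash as their tokens
        lut = {tok: i for i, tok in enumerate(vocab)}
        try:
            flat = [lut[v] for v in y.reshape(-1)]
        except KeyError as exc:
            raise ValueError(f"unknown label {exc.args[0]!r} for this vocabulary") from None
        return np.asarray(flat, dtype=int).reshape(y.shape)

    def _alpha_vector(self, y_idx: np.ndarray, C: int) -> np.ndarray:
        if self.alpha is None:
            return np.ones(C)
        if isinstance(self.alpha, str):
            if self.alpha != "balanced":
                raise ValueError(f"unknown alpha mode {self.alpha!r}")
            counts = np.bincount(y_idx.reshape(-1), minlength=C).astype(float)
            missing = np.flatnonzero(counts == 0)
            if missing.size:
                warnings.warn(
                    "classes absent from training labels get focal alpha 0: "
                    f"{[class_vocabulary(C)[i] for i in missing]}",
                    stacklevel=2,
                )
            inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
            pos = inv[inv > 0]
            return inv / pos.mean() if pos.size else np.ones(C)
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.shape != (C,):
            raise ValueError(f"alpha must have length {C}")
        return alpha

    def fit(self, X: np.ndarray, y: np.ndarray) -> "InsideOutsideSequenceClassifier":
        """Train fc/LSTM/head on sequences X with per-frame labels y.

        X is ``(n, L, 224, 224, 3)`` preprocessed frames or ``(n, L, F)``
        precomputed backbone features; y is ``(n, L)`` class indices or
        tokens.  Runs exactly ``epochs`` full passes; appends one mean
        loss per epoch to ``loss_log_``.
        """
        cfg = self._resolve_config()
        self.config_ = cfg
        self.backbone_weights_ = self._load_backbone()
        vocab = class_vocabulary(cfg.num_classes)
        self.classes_ = np.asarray(vocab, dtype=object)

        feats = self._coerce_X(X)
        if feats.shape[0] == 0:
            raise ValueError("empty training set")
        y_idx = self._encode_y(y, vocab)
        if y_idx.shape != feats.shape[:2]:
            raise ValueError(f"y shape {y_idx.shape} does not match X sequences {feats.shape[:2]}")

        alpha = self._alpha_vector(y_idx, cfg.num_classes)
        self.focal_params_ = FocalLossParams(gamma=self.gamma, alpha=tuple(alpha))

        rng = np.random.default_rng(self.random_state)
        self.weights_ = self._init_weights(cfg, rng)
        self._initial_weights_ = {k: v.copy() for k, v in self.weights_.items()}
        opt = nn.Adam(lr=self.learning_rate, beta1=self.beta1, beta2=self.beta2, eps=self.epsilon)

        n = feats.shape[0]
        self.loss_log_ = []
        for _epoch in range(self.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                sel = perm[start : start + self.batch_size]
                logits, caches = self._forward(feats[sel], training=True, rng=rng)
                loss, dlogits = focal_loss_grad(logits, y_idx[sel], self.focal_params_)
                grads = self._backward(dlogits, caches)
                opt.step(self.weights_, grads)
                losses.append(loss)
            self.loss_log_.append(float(np.mean(losses)))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        feats = self._coerce_X(X)
        logits, _ = self._forward(feats, training=False, rng=None)
        return nn.softmax(logits)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        feats = self._coerce_X(X)
        logits, _ = self._forward(feats, training=False, rng=None)
        return logits

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-frame class tokens, shape (n, L), with the fail-closed tie rule."""
        logits = self.decision_function(X)
        vocab = list(self.classes_)
        return np.asarray(
            [predict_labels(seq_scores, 0, vocab) for seq_scores in logits], dtype=object
        )

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean per-frame accuracy."""
        vocab = list(self.classes_)
        y_idx = self._encode_y(np.asarray(y), vocab)
        pred = self.predict(X)
        pred_idx = np.vectorize({t: i for i, t in enumerate(vocab)}.__getitem__)(pred)
        return float(np.mean(pred_idx == y_idx))

    # -- persistence ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights + config + class vocabulary."""
        check_is_fitted(self, "weights_")
        meta = {
            "params": self.get_params(),
            "config": self.config_.__dict__,
            "classes": list(self.classes_),
            "loss_log": self.loss_log_,
            "focal_alpha": list(self.focal_params_.alpha or ()),
        }
        arrays = {f"w::{k}": v for k, v in self.weights_.items()}
        arrays.update({f"bb::{k}": v for k, v in self.backbone_weights_.items()})
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path, num_classes: int | None = None):
        """Load a checkpoint; refuses a task/num_classes mismatch."""
        archive = np.load(path)
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if num_classes is not None and meta["config"]["num_classes"] != num_classes:
            raise ValueError(
                f"checkpoint has num_classes={meta['config']['num_classes']}, "
                f"requested {num_classes}"
            )
        params = meta["params"]
        params["trainable"] = tuple(params["trainable"])
        est = cls(**params)
        cfg = dict(meta["config"])
        cfg["trainable_set"] = tuple(cfg["trainable_set"])
        est.config_ = ModelConfig(**cfg)
        est.classes_ = np.asarray(meta["classes"], dtype=object)
        est.loss_log_ = meta["loss_log"]
        est.focal_params_ = FocalLossParams(
            gamma=params["gamma"], alpha=tuple(meta["focal_alpha"]) or None
        )
        est.weights_ = {k[3:]: archive[k] for k in archive.files if k.startswith("w::")}
        est.backbone_weights_ = {k[4:]: archive[k] for k in archive.files if k.startswith("bb::")}
        return est
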