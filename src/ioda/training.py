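"""Transfer-learning training loop and stratified cross-validation driver.

Training touches only the layers in the estimator's trainable set — the
frozen backbone never sees a gradient — and runs a fixed number of full
epochs with Adam; there is no early stopping or schedule.  Determinism is
end-to-end: one seed governs fold assignment, weight initialization,
shuffling and dropout, so two identical runs produce bit-identical
weights.

Cross-validation splits by whole video, never by frame: a video's frames
are either all training or all evaluation in a given fold, and a leakage
guard asserts the two video-id sets are disjoint before any gradient
step.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from ioda.annotation import AnnotationTrack, VideoRecord, to_binary
from ioda.dataset import (
    SampledFrame,
    SequenceBatch,
    FoldAssignment,
    make_sequences,
    preprocess,
    sample_timestamps,
    stratified_kfold,
)
from ioda.evaluation import ConfusionMatrix, EvalReport, confusion
from ioda.model import InsideOutsideSequenceClassifier, class_vocabulary

logger = logging.getLogger(__name__)

#: provider(video_id, timestamps) -> (n, H, W, 3) raw frames in [0, 1]
FrameProvider = Callable[[str, Sequence[float]], np.ndarray]


@dataclass
class TrainConfig:
    """Training-loop parameters; one epoch = one full pass over sequences."""

    epochs: int = 5
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 8
    seed: int = 0
    task: str = "binary"  # "binary" | "multiclass"
    gamma: float = 2.0
    sample_rate: float = 1.0
    sequence_length: int = 32
    backbone: str = "tiny_conv"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.task not in ("binary", "multiclass"):
            raise ValueError(f"task must be binary|multiclass, got {self.task!r}")

    @property
    def num_classes(self) -> int:
        return 2 if self.task == "binary" else 5

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def make_estimator(self) -> InsideOutsideSequenceClassifier:
        return InsideOutsideSequenceClassifier(
            backbone=self.backbone,
            num_classes=self.num_classes,
            gamma=self.gamma,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            epsilon=self.epsilon,
            batch_size=self.batch_size,
            random_state=self.seed,
        )


def _sequence_arrays(
    sequences: Sequence[SequenceBatch], task: str
) -> tuple[np.ndarray, np.ndarray]:
    """Stack sequence images/features and encode per-frame labels as tokens."""
    X = np.stack([seq.images() for seq in sequences])
    vocab = class_vocabulary(2 if task == "binary" else 5)
    y = np.empty(X.shape[:2], dtype=object)
    for i, seq in enumerate(sequences):
        for j, label in enumerate(seq.labels()):
            token = to_binary(label).value if task == "binary" else label.value
            if token not in vocab:
                raise ValueError(f"label {token} not in task vocabulary {vocab}")
            y[i, j] = token
    return X, y


def train(
    model: InsideOutsideSequenceClassifier | None,
    train_sequences: Sequence[SequenceBatch],
    config: TrainConfig | None = None,
) -> tuple[InsideOutsideSequenceClassifier, list[float]]:
    """Fit the classifier on training sequences; returns (model, loss log).

    The loss log has one mean focal-loss entry per epoch.  With ``model``
    ``None`` an estimator is built from ``config``.
    """
    config = config or TrainConfig()
    if model is None:
        model = config.make_estimator()
    if not train_sequences:
        raise ValueError("empty training set")
    X, y = _sequence_arrays(train_sequences, config.task)
    model.fit(X, y)
    return model, list(model.loss_log_)


def save_loss_log(log: Sequence[float], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "mean_loss"])
        for epoch, loss in enumerate(log, start=1):
            writer.writerow([epoch, repr(float(loss))])


@dataclass
class FoldResult:
    fold: int
    model: InsideOutsideSequenceClassifier
    report: EvalReport
    loss_log: list[float]
    test_videos: list[str]
    #: per held-out video: predicted class tokens at the sampling rate
    predictions: dict[str, list[str]] = None


@dataclass
class CVResult:
    folds: list[FoldResult]
    fold_assignment: FoldAssignment
    pooled: EvalReport

    @property
    def pooled_cm(self) -> ConfusionMatrix:
        return self.pooled.cm


def _video_frames(
    record: VideoRecord,
    track: AnnotationTrack,
    provider: FrameProvider,
    extractor: InsideOutsideSequenceClassifier,
    sample_rate: float,
) -> list[SampledFrame]:
    """Sample, preprocess and featurize one video's frames (streamed)."""
    timestamps = sample_timestamps(record.duration_s, sample_rate)
    raw = provider(record.video_id, timestamps)
    feats = extractor.extract_features(
        np.stack([preprocess(frame) for frame in raw]).astype(np.float32)
    )
    return [
        SampledFrame(record.video_id, t, feats[i], track.class_at(t))
        for i, t in enumerate(timestamps)
    ]


def run_cross_validation(
    videos: Sequence[VideoRecord],
    tracks: Mapping[str, AnnotationTrack],
    frame_provider: FrameProvider,
    k: int = 5,
    config: TrainConfig | None = None,
) -> CVResult:
    """k-fold stratified CV: train on k−1 folds, evaluate on the held-out one.

    Returns per-fold trained models and reports plus the pooled confusion
    matrix (the elementwise sum of the per-fold matrices).  Backbone
    features are extracted once per video and reused across folds — valid
    because the backbone is frozen and deterministic.
    """
    config = config or TrainConfig()
    fa = stratified_kfold(videos, k=k, seed=config.seed)
    by_id = {v.video_id: v for v in videos}

    extractor = config.make_estimator()
    frames: dict[str, list[SampledFrame]] = {}
    for v in videos:
        frames[v.video_id] = _video_frames(
            v, tracks[v.video_id], frame_provider, extractor, config.sample_rate
        )
        logger.info("featurized %s: %d frames", v.video_id, len(frames[v.video_id]))

    vocab = class_vocabulary(config.num_classes)
    results: list[FoldResult] = []
    pooled_cm: ConfusionMatrix | None = None
    for fold in range(k):
        train_ids, test_ids = fa.train_test_split(fold)
        assert not set(train_ids) & set(test_ids), "leakage: train/test videos overlap"

        train_seqs: list[SequenceBatch] = []
        for vid in train_ids:
            train_seqs.extend(make_sequences(frames[vid], config.sequence_length, "train"))
        assert all(s.video_id in set(train_ids) for s in train_seqs), (
            "leakage: training sequence from a held-out video"
        )
        model, loss_log = train(None, train_seqs, config)
        logger.info("fold %d: trained on %d sequences, losses %s", fold, len(train_seqs), loss_log)

        truth: list[str] = []
        pred: list[str] = []
        predictions: dict[str, list[str]] = {}
        for vid in test_ids:
            t_labels, p_labels = _predict_video(model, frames[vid], config)
            truth.extend(t_labels)
            pred.extend(p_labels)
            predictions[vid] = p_labels
        cm = confusion(truth, pred, vocab)
        report = EvalReport.from_confusion(cm)
        pooled_cm = cm if pooled_cm is None else pooled_cm + cm
        results.append(
            FoldResult(
                fold=fold,
                model=model,
                report=report,
                loss_log=loss_log,
                test_videos=test_ids,
                predictions=predictions,
            )
        )

    pooled = EvalReport.from_confusion(pooled_cm)
    return CVResult(folds=results, fold_assignment=fa, pooled=pooled)


def _predict_video(
    model: InsideOutsideSequenceClassifier,
    video_frames: Sequence[SampledFrame],
    config: TrainConfig,
) -> tuple[list[str], list[str]]:
    """(truth tokens, predicted tokens) for every sampled frame of one video."""
    sequences = make_sequences(video_frames, config.sequence_length, "inference")
    truth: list[str] = []
    pred: list[str] = []
    for seq in sequences:
        keep = len(seq) - seq.pad_count
        X = seq.images()[None]
        p = model.predict(X)[0][:keep]
        pred.extend(str(tok) for tok in p)
        for label in seq.labels()[:keep]:
            truth.append(to_binary(label).value if config.task == "binary" else label.value)
    return truth, pred
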