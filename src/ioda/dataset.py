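"""From videos + annotation tracks to model-ready sequences and CV folds.

Frames are sampled at 1 frame/second by default (classification at native
25 fps would multiply compute 25-fold for near-identical neighboring
frames), resized bilinearly to 224×224 and normalized per channel, then
grouped into non-overlapping 32-frame sequences — the unit the stateless
recurrent classifier consumes.  Cross-validation folds are built per
video (never per frame) and balanced greedily on operation type and total
duration.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from PIL import Image

from ioda.annotation import AnnotationTrack, FrameClass, VideoRecord

#: Default per-channel normalization constants (frame values in [0,1]).
DEFAULT_MEAN = (0.485, 0.456, 0.456)
DEFAULT_SD = (0.229, 0.224, 0.225)

#: Model input side length in pixels.
INPUT_SIZE = 224

#: Default sequence length L (seconds of video at 1 fps sampling).
SEQUENCE_LENGTH = 32


@dataclass
class SampledFrame:
    """One preprocessed frame with its ground-truth label."""

    video_id: str
    timestamp_s: float
    image: np.ndarray  # (224, 224, 3) normalized; or backbone feature vector
    label: FrameClass | None


@dataclass
class SequenceBatch:
    """Ordered run of L frames from one video; the model's input unit.

    ``pad_count`` trailing frames are repeats of the final real frame,
    used only at inference so every frame of a video gets classified.
    """

    frames: list[SampledFrame]
    pad_count: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty sequence")
        if not 0 <= self.pad_count < len(self.frames):
            raise ValueError(f"pad_count {self.pad_count} must be < L={len(self.frames)}")
        vids = {f.video_id for f in self.frames}
        if len(vids) != 1:
            raise ValueError(f"sequence mixes videos: {sorted(vids)}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def video_id(self) -> str:
        return self.frames[0].video_id

    def images(self) -> np.ndarray:
        return np.stack([f.image for f in self.frames])

    def labels(self) -> list[FrameClass | None]:
        return [f.label for f in self.frames]


def sample_timestamps(duration_s: float, sample_rate: float = 1.0) -> list[float]:
    """Frame-sampling timestamps ``k / sample_rate`` within ``[0, duration_s)``."""
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if sample_rate <= 0:
        raise ValueError(f"sample_rate must be positive, got {sample_rate}")
    n = int(math.floor(duration_s * sample_rate + 1e-9))
    return [k / sample_rate for k in range(n)]


def preprocess(
    frame: np.ndarray,
    mean: Sequence[float] = DEFAULT_MEAN,
    sd: Sequence[float] = DEFAULT_SD,
) -> np.ndarray:
    """Bilinear-resize a (H, W, 3) frame in [0,1] to 224×224 and normalize.

    Output is float32 ``(x - mean) / sd`` per channel.
    """
    frame = np.asarray(frame, dtype=np.float32)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) frame, got shape {frame.shape}")
    if frame.shape[0] < 1 or frame.shape[1] < 1:
        raise ValueError("frame must have at least one pixel")
    mean = np.asarray(mean, dtype=np.float32)
    sd = np.asarray(sd, dtype=np.float32)
    if np.any(sd == 0):
        raise ValueError("normalization sd components must be nonzero")
    if frame.shape[:2] != (INPUT_SIZE, INPUT_SIZE):
        channels = [
            np.asarray(
                Image.fromarray(frame[:, :, c], mode="F").resize(
                    (INPUT_SIZE, INPUT_SIZE), Image.BILINEAR
                )
            )
            for c in range(3)
        ]
        frame = np.stack(channels, axis=-1)
    return (frame - mean) / sd


def make_sequences(
    frames: Sequence[SampledFrame],
    L: int = SEQUENCE_LENGTH,
    mode: Literal["train", "inference"] = "train",
) -> list[SequenceBatch]:
    """Chunk a video's time-ordered frames into non-overlapping L-frame runs.

    Train mode drops a trailing remainder shorter than L; inference mode
    pads it by repeating the final frame (recording ``pad_count``) so no
    frame goes unclassified.
    """
    if mode not in ("train", "inference"):
        raise ValueError(f"unknown mode {mode!r}")
    frames = list(frames)
    if not frames and mode == "inference":
        raise ValueError("no frames to classify")
    out: list[SequenceBatch] = []
    for start in range(0, len(frames) - L + 1, L):
        out.append(SequenceBatch(frames[start : start + L]))
    rem = len(frames) % L
    if rem and mode == "inference":
        tail = frames[len(frames) - rem :]
        pad = [tail[-1]] * (L - rem)
        out.append(SequenceBatch(tail + pad, pad_count=L - rem))
    return out


@dataclass
class FoldAssignment:
    """Video → fold index map for k-fold cross-validation."""

    k: int
    assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v: f for v, f in self.assignment.items() if not 0 <= f < self.k}
        if bad:
            raise ValueError(f"fold indices out of range: {bad}")

    def fold_videos(self, fold: int) -> list[str]:
        return sorted(v for v, f in self.assignment.items() if f == fold)

    def train_test_split(self, fold: int) -> tuple[list[str], list[str]]:
        test = self.fold_videos(fold)
        train = sorted(v for v, f in self.assignment.items() if f != fold)
        return train, test

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["video_id", "fold"])
            for vid in sorted(self.assignment):
                writer.writerow([vid, self.assignment[vid]])

    @classmethod
    def load(cls, path: str | Path) -> "FoldAssignment":
        with Path(path).open(newline="") as fh:
            rows = list(csv.DictReader(fh))
        assignment = {r["video_id"]: int(r["fold"]) for r in rows}
        return cls(k=max(assignment.values()) + 1, assignment=assignment)


def stratified_kfold(
    videos: Sequence[VideoRecord], k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Assign whole videos to k folds, balancing operation type and duration.

    Greedy rule: within each operation type, videos sorted by duration
    (descending) are assigned to the fold with the smallest running total
    duration, ties broken by fold index.  The seed only permutes the order
    in which operation types are visited and breaks exact duration ties,
    so the balance property is deterministic per (inputs, seed).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(videos):
        raise ValueError(f"k={k} exceeds number of videos ({len(videos)})")
    ids = [v.video_id for v in videos]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate video_id in roster")

    rng = np.random.default_rng(seed)
    by_type: dict[str, list[VideoRecord]] = {}
    for v in videos:
        by_type.setdefault(v.operation_type, []).append(v)

    totals = np.zeros(k)
    assignment: dict[str, int] = {}
    type_order = sorted(by_type)
    rng.shuffle(type_order)
    for op_type in type_order:
        group = list(by_type[op_type])
        rng.shuffle(group)  # breaks exact-duration ties reproducibly
        group.sort(key=lambda v: -v.duration_s)
        for v in group:
            fold = int(np.argmin(totals))  # argmin takes the lowest index on ties
            assignment[v.video_id] = fold
            totals[fold] += v.duration_s

    fa = FoldAssignment(k=k, assignment=assignment)
    for fold in range(k):
        if not fa.fold_videos(fold):
            # only possible when k is close to len(videos) and durations are skewed
            raise ValueError(f"fold {fold} is empty; reduce k")
    return fa


def extract_sampled_frames(
    track: AnnotationTrack,
    frames: Iterable[np.ndarray],
    timestamps: Sequence[float],
    mean: Sequence[float] = DEFAULT_MEAN,
    sd: Sequence[float] = DEFAULT_SD,
) -> list[SampledFrame]:
    """Preprocess raw frames sampled at ``timestamps`` and attach labels."""
    out = []
    for t, frame in zip(timestamps, frames):
        out.append(
            SampledFrame(
                video_id=track.video_id,
                timestamp_s=t,
                image=preprocess(frame, mean, sd),
                label=track.class_at(t),
            )
        )
    return out
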