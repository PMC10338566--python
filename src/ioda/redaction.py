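"""Temporal smoothing, label expansion and frame censoring.

Classification runs at 1 frame/second; anonymization must cover every
native frame.  The pipeline is: optionally smooth the sampled binary
timeline (surgical scenes persist for seconds, so an isolated one-second
island is almost surely a classifier glitch), expand each sampled label
over the native frames of its second, then censor every OUTSIDE frame.

Smoothing comes in two flavours.  ``symmetric`` reassigns any interior
run shorter than ``min_island_s`` whose two neighbours agree, in either
direction.  ``privacy_safe`` (the default) applies the same rule but
never flips an OUTSIDE run to INSIDE: a spurious inside island inside an
outside block is removed (more censoring, no risk), while a genuine
short outside glimpse is preserved for censoring even if the classifier
flagged it for only a second.  Censoring itself fails closed — a
label/frame count mismatch aborts before anything is written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from ioda.annotation import BinaryClass
from ioda.video_io import read_video, write_video


@dataclass
class LabelTimeline:
    """Binary labels at sampled timestamps ``k / sample_rate``."""

    sample_rate: float
    labels: list[BinaryClass]

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.labels = [BinaryClass(l) for l in self.labels]

    def __len__(self) -> int:
        return len(self.labels)

    def runs(self) -> list[tuple[int, int, BinaryClass]]:
        """Maximal constant-label runs as (start, end) index pairs, half-open."""
        runs = []
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] is not self.labels[start]:
                runs.append((start, i, self.labels[start]))
                start = i
        return runs

    def n_switches(self) -> int:
        return max(0, len(self.runs()) - 1)


@dataclass(frozen=True)
class RedactionPolicy:
    """How to censor and whether/how to smooth first."""

    mode: Literal["black", "blur"] = "black"
    min_island_s: float = 2.0
    smoothing: Literal["off", "symmetric", "privacy_safe"] = "privacy_safe"

    def __post_init__(self) -> None:
        if self.mode not in ("black", "blur"):
            raise ValueError(f"unknown censoring mode {self.mode!r}")
        if self.min_island_s < 0:
            raise ValueError("min_island_s must be >= 0")
        if self.smoothing not in ("off", "symmetric", "privacy_safe"):
            raise ValueError(f"unknown smoothing {self.smoothing!r}")


def smooth(timeline: LabelTimeline, policy: RedactionPolicy) -> LabelTimeline:
    """Reassign short interior label islands to their surrounding label.

    A maximal run is an island when it is strictly shorter than
    ``min_island_s`` and its two neighbouring runs share a label; edge
    runs are never touched.  ``privacy_safe`` additionally never
    reassigns an OUTSIDE run to INSIDE.  The rule is iterated to a
    fixpoint (flipping one island can merge runs and expose another).
    """
    if policy.smoothing == "off":
        return LabelTimeline(timeline.sample_rate, list(timeline.labels))
    labels = list(timeline.labels)
    min_frames = policy.min_island_s * timeline.sample_rate
    while True:
        tl = LabelTimeline(timeline.sample_rate, labels)
        runs = tl.runs()
        changed = False
        for r, (start, end, label) in enumerate(runs):
            if r == 0 or r == len(runs) - 1:
                continue  # edge runs are never reassigned
            if (end - start) >= min_frames:
                continue
            prev_label = runs[r - 1][2]
            next_label = runs[r + 1][2]
            if prev_label is not next_label:
                continue
            if policy.smoothing == "privacy_safe" and label is BinaryClass.OUTSIDE:
                continue
            labels[start:end] = [prev_label] * (end - start)
            changed = True
            break  # re-derive runs after each change: fixpoint iteration
        if not changed:
            return LabelTimeline(timeline.sample_rate, labels)


def expand(
    timeline: LabelTimeline, native_fps: float, frame_count: int
) -> list[BinaryClass]:
    """Per-native-frame labels: frame ``i`` takes the label of the sampled
    timestamp containing ``i / native_fps``; trailing frames keep the last
    label."""
    if not timeline.labels:
        raise ValueError("empty timeline")
    if frame_count < 0:
        raise ValueError("frame_count must be >= 0")
    out = []
    last = len(timeline.labels) - 1
    for i in range(frame_count):
        k = int(np.floor(i / native_fps * timeline.sample_rate + 1e-9))
        out.append(timeline.labels[min(k, last)])
    return out


def _pixelate(frame: np.ndarray, block: int) -> np.ndarray:
    """Heavy box blur by block-averaging; idempotent by construction."""
    h, w = frame.shape[:2]
    out = frame.copy()
    for y0 in range(0, h, block):
        for x0 in range(0, w, block):
            patch = frame[y0 : y0 + block, x0 : x0 + block]
            out[y0 : y0 + block, x0 : x0 + block] = patch.mean(axis=(0, 1))
    return out


def censor_frame(frame: np.ndarray, mode: str) -> np.ndarray:
    if mode == "black":
        return np.zeros_like(frame)
    if mode == "blur":
        block = max(1, frame.shape[1] // 8)  # kernel ≥ 1/8 frame width
        return _pixelate(frame, block)
    raise ValueError(f"unknown censoring mode {mode!r}")


def censored_ranges(frame_labels: Sequence[BinaryClass]) -> list[tuple[int, int]]:
    """Half-open native-frame index ranges labeled OUTSIDE."""
    ranges = []
    start = None
    for i, label in enumerate(frame_labels):
        if label is BinaryClass.OUTSIDE and start is None:
            start = i
        elif label is not BinaryClass.OUTSIDE and start is not None:
            ranges.append((start, i))
            start = None
    if start is not None:
        ranges.append((start, len(frame_labels)))
    return ranges


@dataclass
class RedactionManifest:
    """Machine-readable record of exactly what was censored."""

    video_id: str
    mode: str
    smoothing: str
    frame_count: int
    censored_ranges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def censored_frames(self) -> int:
        return sum(e - s for s, e in self.censored_ranges)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "video_id": self.video_id,
            "mode": self.mode,
            "smoothing": self.smoothing,
            "frame_count": self.frame_count,
            "censored_frames": self.censored_frames,
            "censored_ranges": [[s, e] for s, e in self.censored_ranges],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def redact(
    video: str | Path,
    frame_labels: Sequence[BinaryClass | str],
    policy: RedactionPolicy = RedactionPolicy(),
    out: str | Path | None = None,
    fps: float = 25.0,
    video_id: str | None = None,
) -> tuple[Path, RedactionManifest]:
    """Censor every OUTSIDE-labeled frame of ``video``; write video + manifest.

    ``frame_labels`` must already be at native fps (see :func:`expand`) and
    match the decoded frame count exactly — a mismatch is a hard error and
    nothing is written.  INSIDE frames pass through unmodified before
    re-encoding.
    """
    video = Path(video)
    frames = read_video(video)
    labels = [BinaryClass(l) for l in frame_labels]
    if len(labels) != len(frames):
        raise ValueError(
            f"label count {len(labels)} != frame count {len(frames)}; refusing to write"
        )
    ranges = censored_ranges(labels)
    for s, e in ranges:
        for i in range(s, e):
            frames[i] = censor_frame(frames[i], policy.mode)
    if out is None:
        out = video.with_name(video.stem + ".anon" + video.suffix)
    path = write_video(out, frames, fps)
    manifest = RedactionManifest(
        video_id=video_id or video.stem,
        mode=policy.mode,
        smoothing=policy.smoothing,
        frame_count=len(frames),
        censored_ranges=ranges,
    )
    manifest.to_json(Path(path).with_suffix(".manifest.json"))
    return path, manifest
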