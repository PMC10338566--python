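"""Frame-class taxonomy and per-video interval annotations.

Every frame of a laparoscopic video belongs to one of five classes: two
inside the abdomen (``ABDOMINAL_CAVITY``, ``TROCAR`` — the view down a
solid port) and three outside (``OUTSIDE`` — the operating field seen
directly, ``CLEANING`` — outside with the intention of wiping the lens,
``TRANSLUCENT_TROCAR`` — skin visible through a translucent port wall).
The five classes map surjectively onto the binary inside/outside outcome
that drives anonymization; outside is the privacy-critical side.

Annotations are carried as gap-free, non-overlapping, half-open time
intervals ``[start_s, end_s)`` tiling ``[0, duration_s)``.  Frame ``i``
(0-based) at ``fps`` frames/second has timestamp ``i / fps``, so half-open
intervals count every frame exactly once.  The on-disk format is a plain
CSV (``video_id,start_s,end_s,label``); unknown class tokens are hard
errors — a privacy pipeline must fail closed.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class AnnotationError(ValueError):
    """Raised when an annotation track violates its invariants."""


class FrameClass(str, Enum):
    """Five-way frame label; order fixes the class-index vocabulary."""

    ABDOMINAL_CAVITY = "ABDOMINAL_CAVITY"
    TROCAR = "TROCAR"
    OUTSIDE = "OUTSIDE"
    CLEANING = "CLEANING"
    TRANSLUCENT_TROCAR = "TRANSLUCENT_TROCAR"


class BinaryClass(str, Enum):
    """Binary outcome; OUTSIDE is the privacy-critical class."""

    INSIDE = "INSIDE"
    OUTSIDE = "OUTSIDE"


#: Surjective mapping of the five-way taxonomy onto inside/outside.
BINARY_MAP: Mapping[FrameClass, BinaryClass] = {
    FrameClass.ABDOMINAL_CAVITY: BinaryClass.INSIDE,
    FrameClass.TROCAR: BinaryClass.INSIDE,
    FrameClass.OUTSIDE: BinaryClass.OUTSIDE,
    FrameClass.CLEANING: BinaryClass.OUTSIDE,
    FrameClass.TRANSLUCENT_TROCAR: BinaryClass.OUTSIDE,
}

#: The four procedure categories used for stratification.
CATEGORIES = ("cholecystectomy", "upper_gastrointestinal", "colorectal", "miscellaneous")

_TIME_EPS = 1e-6  # tolerance for float times parsed from CSV


def to_binary(label: FrameClass) -> BinaryClass:
    """Collapse a five-way frame label to the binary inside/outside outcome."""
    return BINARY_MAP[FrameClass(label)]


@dataclass(frozen=True)
class AnnotationInterval:
    """Half-open labeled time interval ``[start_s, end_s)`` in seconds."""

    start_s: float
    end_s: float
    label: FrameClass

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise AnnotationError(f"interval start {self.start_s} < 0")
        if not self.end_s > self.start_s:
            raise AnnotationError(
                f"interval end {self.end_s} must exceed start {self.start_s}"
            )
        object.__setattr__(self, "label", FrameClass(self.label))

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AnnotationTrack:
    """Gap-free label intervals for one video.

    Invariants (enforced by :meth:`validate`, normal form by
    :meth:`normalize`): intervals are sorted, pairwise disjoint, exactly
    tile ``[0, duration_s)``, and adjacent intervals carry different
    labels.
    """

    video_id: str
    duration_s: float
    fps: float
    intervals: list[AnnotationInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise AnnotationError(f"duration_s {self.duration_s} < 0")
        if self.fps <= 0:
            raise AnnotationError(f"fps {self.fps} must be positive")

    # -- validation / normal form -------------------------------------------------

    def validate(self) -> "AnnotationTrack":
        """Check sortedness, disjointness and exact tiling of [0, duration)."""
        ivs = sorted(self.intervals, key=lambda iv: iv.start_s)
        if not ivs:
            if self.duration_s > _TIME_EPS:
                raise AnnotationError(
                    f"gap in coverage: [0, {self.duration_s}) has no annotation"
                )
            return self
        if ivs[0].start_s > _TIME_EPS:
            raise AnnotationError(f"gap in coverage: [0, {ivs[0].start_s}) uncovered")
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start_s < prev.end_s - _TIME_EPS:
                raise AnnotationError(
                    "overlapping intervals: "
                    f"[{prev.start_s}, {prev.end_s}) {prev.label.value} and "
                    f"[{cur.start_s}, {cur.end_s}) {cur.label.value} overlap at t={cur.start_s}"
                )
            if cur.start_s > prev.end_s + _TIME_EPS:
                raise AnnotationError(
                    f"gap in coverage: [{prev.end_s}, {cur.start_s}) uncovered"
                )
        if abs(ivs[-1].end_s - self.duration_s) > _TIME_EPS:
            if ivs[-1].end_s < self.duration_s:
                raise AnnotationError(
                    f"gap in coverage: [{ivs[-1].end_s}, {self.duration_s}) uncovered"
                )
            raise AnnotationError(
                f"interval end {ivs[-1].end_s} exceeds track duration {self.duration_s}"
            )
        return self

    def normalize(self) -> "AnnotationTrack":
        """Return a validated copy with equal-label neighbors merged.

        Idempotent: normalizing a normalized track is the identity.
        """
        self.validate()
        ivs = sorted(self.intervals, key=lambda iv: iv.start_s)
        merged: list[AnnotationInterval] = []
        for iv in ivs:
            if merged and merged[-1].label is iv.label:
                merged[-1] = replace(merged[-1], end_s=iv.end_s)
            else:
                merged.append(iv)
        # snap boundaries: first starts at 0, chain exactly, last ends at duration
        snapped: list[AnnotationInterval] = []
        t = 0.0
        for i, iv in enumerate(merged):
            end = self.duration_s if i == len(merged) - 1 else iv.end_s
            snapped.append(AnnotationInterval(t, end, iv.label))
            t = end
        return AnnotationTrack(self.video_id, self.duration_s, self.fps, snapped)

    # -- queries ------------------------------------------------------------------

    def class_at(self, t: float) -> FrameClass:
        """Label of the unique half-open interval containing time ``t``."""
        if not (0 <= t < self.duration_s):
            raise AnnotationError(
                f"t={t} outside [0, {self.duration_s}) for video {self.video_id!r}"
            )
        for iv in self.intervals:
            if iv.start_s <= t < iv.end_s:
                return iv.label
        # only reachable on an invalid (gappy) track
        raise AnnotationError(f"no interval covers t={t}; track not validated?")

    def n_frames(self, fps: float | None = None) -> int:
        """Number of frame indices ``i`` with ``i / fps < duration_s``."""
        fps = self.fps if fps is None else fps
        return _frame_count(self.duration_s, fps)

    def frame_labels(self, fps: float | None = None) -> list[FrameClass]:
        """Per-frame labels at the given rate (default: native fps)."""
        fps = self.fps if fps is None else fps
        out: list[FrameClass] = []
        for iv in self.intervals:
            lo = _first_frame_at_or_after(iv.start_s, fps)
            hi = min(_first_frame_at_or_after(iv.end_s, fps), self.n_frames(fps))
            out.extend([iv.label] * (hi - lo))
        return out


@dataclass(frozen=True)
class VideoRecord:
    """Catalog entry for one video: procedure metadata and geometry."""

    video_id: str
    category: str
    operation_type: str
    duration_s: float
    fps: float
    width: int = 960
    height: int = 540

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise AnnotationError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.duration_s <= 0:
            raise AnnotationError("duration_s must be positive")
        if self.fps <= 0:
            raise AnnotationError("fps must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "VideoRecord":
        return cls(**json.loads(Path(path).read_text()))


# -- frame-index arithmetic (shared with dataset/redaction) -----------------------


def _frame_count(duration_s: float, fps: float) -> int:
    return int(round(duration_s * fps))


def _first_frame_at_or_after(t: float, fps: float) -> int:
    """Smallest frame index i with i/fps >= t (float-tolerant)."""
    return int(math.ceil(t * fps - _TIME_EPS))


# -- file I/O ---------------------------------------------------------------------

_CSV_HEADER = ["video_id", "start_s", "end_s", "label"]


def load_track(
    path: str | Path,
    duration_s: float | None = None,
    fps: float = 25.0,
) -> AnnotationTrack:
    """Read an annotation CSV and return the normalized track.

    The CSV has header ``video_id,start_s,end_s,label``; every row must
    carry the same ``video_id``.  ``duration_s`` defaults to the largest
    interval end.  Unknown class tokens, overlaps and coverage gaps are
    hard errors.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _CSV_HEADER:
            raise AnnotationError(
                f"{path}: expected header {','.join(_CSV_HEADER)!r}, got {reader.fieldnames}"
            )
        rows = list(reader)

    video_id = rows[0]["video_id"] if rows else path.stem
    intervals = []
    for row in rows:
        token = row["label"].strip()
        try:
            label = FrameClass(token)
        except ValueError:
            raise AnnotationError(f"{path}: unknown class token {token!r}") from None
        intervals.append(AnnotationInterval(float(row["start_s"]), float(row["end_s"]), label))
    if duration_s is None:
        duration_s = max((iv.end_s for iv in intervals), default=0.0)
    return AnnotationTrack(video_id, duration_s, fps, intervals).normalize()


def save_track(track: AnnotationTrack, path: str | Path) -> None:
    """Write a track as an annotation CSV; inverse of :func:`load_track`."""
    track.validate()
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for iv in track.intervals:
            writer.writerow([track.video_id, repr(iv.start_s), repr(iv.end_s), iv.label.value])


def class_distribution(
    tracks: Iterable[AnnotationTrack] | Sequence[AnnotationTrack],
    fps: float | None = None,
) -> dict[FrameClass, tuple[int, float]]:
    """Per-class frame counts and fractions over a set of tracks.

    Frames are counted at frame timestamps ``i / fps`` (native fps unless
    overridden); fractions sum to 1.
    """
    tracks = list(tracks)
    if not tracks:
        raise AnnotationError("class_distribution of an empty track list")
    if fps is not None and fps <= 0:
        raise AnnotationError("fps must be positive")
    counts = {c: 0 for c in FrameClass}
    for track in tracks:
        rate = track.fps if fps is None else fps
        n = track.n_frames(rate)
        for iv in track.intervals:
            lo = _first_frame_at_or_after(iv.start_s, rate)
            hi = min(_first_frame_at_or_after(iv.end_s, rate), n)
            counts[iv.label] += max(0, hi - lo)
    total = sum(counts.values())
    if total == 0:
        raise AnnotationError("tracks contain no frames")
    return {c: (counts[c], counts[c] / total) for c in FrameClass}
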