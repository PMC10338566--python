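"""Seeded synthetic laparoscopic-like video with ground-truth annotation.

Real surgical video is privacy-restricted, so the pipeline is exercised on
synthetic footage that reproduces the *structure* of the task rather than
its photorealism: long inside-dominant recordings composed of contiguous
multi-second class segments, a heavy class imbalance (abdominal cavity
~81%, outside ~16%, the remaining three classes ~2.5% of frames), brief
translucent-trocar episodes of a second or two, cross-faded transitions
between segments (the empirically hard case), and seeded per-frame noise.

Appearance is deliberately simple — warm red cavity texture, dark trocar
vignette, cool drape/skin for the outside classes, horizontal motion blur
for cleaning — but guarantees a separability floor: cavity and outside
mean colors differ by ≥ 0.2 in at least one channel, so the learning task
is solvable at desk scale and a failing classifier indicates a pipeline
bug, not an impossible task.

Everything is deterministic given the scenario seed: the same
:class:`ScenarioSpec` and timestamp always render the same frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy import ndimage

from ioda.annotation import AnnotationInterval, AnnotationTrack, FrameClass
from ioda.video_io import write_video


@dataclass(frozen=True)
class ClassAppearance:
    """Rendering parameters for one frame class."""

    mean_color: tuple[float, float, float]
    texture_scale_px: float = 24.0
    texture_amplitude: float = 0.12
    vignette_radius_frac: float = 0.0  # > 0 → trocar-style circular mask
    vignette_floor: float = 0.08
    skin_patch: bool = False
    skin_color: tuple[float, float, float] = (0.82, 0.62, 0.52)
    motion_blur_px: int = 0
    drift_px_per_s: float = 3.0


@dataclass(frozen=True)
class AppearanceModel:
    """Per-class appearance; defaults satisfy the separability floor.

    The cavity mean color is red-dominant and the outside mean color
    blue-dominant, differing by ≥ 0.2 in at least one channel, so mean
    channel statistics alone separate inside from outside.
    """

    classes: Mapping[FrameClass, ClassAppearance] = field(
        default_factory=lambda: dict(DEFAULT_APPEARANCE)
    )

    def __post_init__(self) -> None:
        cav = np.asarray(self.classes[FrameClass.ABDOMINAL_CAVITY].mean_color)
        out = np.asarray(self.classes[FrameClass.OUTSIDE].mean_color)
        if float(np.max(np.abs(cav - out))) < 0.2:
            raise ValueError(
                "appearance violates separability floor: cavity and outside "
                "mean colors must differ by >= 0.2 in some channel"
            )


DEFAULT_APPEARANCE: dict[FrameClass, ClassAppearance] = {
    FrameClass.ABDOMINAL_CAVITY: ClassAppearance(
        mean_color=(0.58, 0.18, 0.14), texture_scale_px=28.0, texture_amplitude=0.14
    ),
    FrameClass.TROCAR: ClassAppearance(
        mean_color=(0.42, 0.14, 0.12),
        texture_scale_px=16.0,
        texture_amplitude=0.08,
        vignette_radius_frac=0.38,
    ),
    FrameClass.OUTSIDE: ClassAppearance(
        mean_color=(0.30, 0.42, 0.66),
        texture_scale_px=40.0,
        texture_amplitude=0.10,
        skin_patch=True,
    ),
    FrameClass.CLEANING: ClassAppearance(
        mean_color=(0.36, 0.46, 0.62),
        texture_scale_px=20.0,
        texture_amplitude=0.16,
        skin_patch=True,
        motion_blur_px=9,
    ),
    FrameClass.TRANSLUCENT_TROCAR: ClassAppearance(
        mean_color=(0.55, 0.55, 0.68),
        texture_scale_px=14.0,
        texture_amplitude=0.08,
        vignette_radius_frac=0.38,
        vignette_floor=0.75,
        skin_patch=True,
    ),
}

#: Empirical class shares of annotated frames in long laparoscopic video.
DEFAULT_CLASS_FRACTIONS: dict[FrameClass, float] = {
    FrameClass.ABDOMINAL_CAVITY: 0.8139,
    FrameClass.TROCAR: 0.0139,
    FrameClass.OUTSIDE: 0.1607,
    FrameClass.CLEANING: 0.0108,
    FrameClass.TRANSLUCENT_TROCAR: 0.0007,
}

#: Mean segment length in seconds per class (inside runs long, translucent
#: trocar episodes ~1–3 s); lengths are drawn uniformly in [0.5, 1.5]×mean
#: so the expected length equals the mean.
DEFAULT_SEGMENT_MEAN_S: dict[FrameClass, float] = {
    FrameClass.ABDOMINAL_CAVITY: 40.0,
    FrameClass.TROCAR: 4.0,
    FrameClass.OUTSIDE: 15.0,
    FrameClass.CLEANING: 5.0,
    FrameClass.TRANSLUCENT_TROCAR: 2.0,
}

_MIN_TAIL_S = 1.0  # shorter leftover tails are absorbed into the previous segment


@dataclass
class ScenarioSpec:
    """Seedable script for one synthetic video: ordered (class, duration) segments."""

    video_id: str
    fps: float = 5.0
    width: int = 160
    height: int = 90
    segments: list[tuple[FrameClass, float]] = field(default_factory=list)
    transition_s: float = 0.3
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        self.segments = [(FrameClass(c), float(d)) for c, d in self.segments]
        for c, d in self.segments:
            if d <= 0:
                raise ValueError(f"segment duration must be positive, got {d} for {c}")
        if self.segments:
            shortest = min(d for _, d in self.segments)
            if self.transition_s >= shortest / 2:
                raise ValueError(
                    f"transition_s={self.transition_s} must be < half the shortest "
                    f"segment ({shortest} s)"
                )

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.segments))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def track(self) -> AnnotationTrack:
        """Ground-truth annotation: segments as half-open intervals, normalized."""
        intervals = []
        t = 0.0
        for c, d in self.segments:
            intervals.append(AnnotationInterval(t, t + d, c))
            t += d
        return AnnotationTrack(self.video_id, t, self.fps, intervals).normalize()

    # -- YAML round-trip ----------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "video_id": self.video_id,
            "fps": self.fps,
            "width": self.width,
            "height": self.height,
            "transition_s": self.transition_s,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "segments": [[c.value, d] for c, d in self.segments],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        doc = yaml.safe_load(Path(path).read_text())
        doc["segments"] = [(FrameClass(c), float(d)) for c, d in doc["segments"]]
        return cls(**doc)


def sample_scenario(
    rng_seed: int,
    fractions: Mapping[FrameClass, float] | None = None,
    segment_mean_s: Mapping[FrameClass, float] | None = None,
    duration_s: float = 300.0,
    video_id: str | None = None,
    **spec_kwargs,
) -> ScenarioSpec:
    """Draw a segment script whose expected class time shares match ``fractions``.

    Segments are sampled as a renewal process: class ``c`` is drawn with
    probability proportional to ``fractions[c] / mean_length[c]`` and its
    length uniformly in [0.5, 1.5] × mean, so the long-run time share of
    each class equals its requested fraction.  Zero-fraction classes never
    appear; negative fractions are rejected.
    """
    fractions = dict(DEFAULT_CLASS_FRACTIONS if fractions is None else fractions)
    means = dict(DEFAULT_SEGMENT_MEAN_S if segment_mean_s is None else segment_mean_s)
    for c, f in fractions.items():
        if f < 0:
            raise ValueError(f"class fraction for {c} is negative: {f}")
    total = sum(fractions.values())
    if total <= 0:
        raise ValueError("class fractions must have a positive sum")
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"class fractions must sum to 1, got {total}")

    classes = [c for c in FrameClass if fractions.get(c, 0.0) > 0]
    weights = np.array([fractions[c] / means[c] for c in classes])
    weights = weights / weights.sum()

    rng = np.random.default_rng(rng_seed)
    segments: list[tuple[FrameClass, float]] = []
    t = 0.0
    while t < duration_s - 1e-9:
        remaining = duration_s - t
        if remaining < _MIN_TAIL_S and segments:
            # absorb a sub-second tail into the previous segment
            c, d = segments[-1]
            segments[-1] = (c, d + remaining)
            break
        c = classes[int(rng.choice(len(classes), p=weights))]
        length = float(means[c] * rng.uniform(0.5, 1.5))
        if length >= remaining or remaining - length < _MIN_TAIL_S:
            length = remaining  # close out the video
        segments.append((c, length))
        t += length
    # merge adjacent equal labels (time shares unchanged)
    merged: list[tuple[FrameClass, float]] = []
    for c, d in segments:
        if merged and merged[-1][0] is c:
            merged[-1] = (c, merged[-1][1] + d)
        else:
            merged.append((c, d))
    if video_id is None:
        video_id = f"synth-{rng_seed}"
    return ScenarioSpec(video_id=video_id, segments=merged, seed=rng_seed, **spec_kwargs)


# -- rendering --------------------------------------------------------------------


def _segment_at(spec: ScenarioSpec, t: float) -> tuple[int, float, float]:
    """(segment index, segment start, segment end) containing time t."""
    if not (0 <= t < spec.duration_s):
        raise ValueError(f"t={t} outside [0, {spec.duration_s})")
    start = 0.0
    for i, (_, d) in enumerate(spec.segments):
        if t < start + d or i == len(spec.segments) - 1:
            return i, start, start + d
        start += d
    raise AssertionError("unreachable")


def _class_texture(spec: ScenarioSpec, cls: FrameClass, app: ClassAppearance) -> np.ndarray:
    """Static smooth random field for one class, deterministic per (spec, class)."""
    rng = np.random.default_rng([spec.seed, 101, list(FrameClass).index(cls)])
    h, w = spec.height, spec.width
    field_ = rng.standard_normal((h, w))
    field_ = ndimage.gaussian_filter(field_, sigma=app.texture_scale_px / 4.0, mode="wrap")
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    return field_


def _render_class(spec: ScenarioSpec, cls: FrameClass, t: float, model: AppearanceModel) -> np.ndarray:
    app = model.classes[cls]
    h, w = spec.height, spec.width
    tex = _class_texture(spec, cls, app)
    shift = int(round(app.drift_px_per_s * t))
    tex = np.roll(tex, shift, axis=1)
    img = np.asarray(app.mean_color)[None, None, :] + app.texture_amplitude * tex[:, :, None]

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    if app.skin_patch:
        # elliptical skin-toned patch, slowly drifting
        px = cx + 0.25 * w * np.sin(0.31 * t)
        py = cy + 0.2 * h * np.cos(0.17 * t)
        mask = ((xx - px) / (0.22 * w)) ** 2 + ((yy - py) / (0.28 * h)) ** 2 < 1.0
        img = np.where(mask[:, :, None], np.asarray(app.skin_color)[None, None, :], img)

    if app.vignette_radius_frac > 0:
        r = np.hypot((yy - cy) / h, (xx - cx) / h)  # normalized by height
        edge = app.vignette_radius_frac
        ring = np.clip((r - edge) / 0.05, 0.0, 1.0)  # 0 inside disc → 1 in ring
        gain = 1.0 - (1.0 - app.vignette_floor) * ring
        img = img * gain[:, :, None]

    if app.motion_blur_px > 1:
        img = ndimage.uniform_filter1d(img, size=app.motion_blur_px, axis=1, mode="wrap")

    return img


def render_frame(
    spec: ScenarioSpec, t: float, model: AppearanceModel | None = None
) -> np.ndarray:
    """Render the frame at time ``t`` as float (H, W, 3) in [0, 1].

    Deterministic given (spec, t).  Within ``transition_s`` of a segment
    boundary the two neighboring class renders are linearly cross-faded;
    the ground-truth label stays with the segment owning the timestamp.
    """
    model = AppearanceModel() if model is None else model
    idx, seg_start, seg_end = _segment_at(spec, t)
    cls = spec.segments[idx][0]
    img = _render_class(spec, cls, t, model)

    tr = spec.transition_s
    if tr > 0:
        if idx > 0 and (t - seg_start) < tr:
            prev_cls = spec.segments[idx - 1][0]
            if prev_cls is not cls:
                # fade runs across [seg_start - tr, seg_start + tr]
                alpha = 0.5 + (t - seg_start) / (2 * tr)
                img = alpha * img + (1 - alpha) * _render_class(spec, prev_cls, t, model)
        elif idx < len(spec.segments) - 1 and (seg_end - t) < tr:
            next_cls = spec.segments[idx + 1][0]
            if next_cls is not cls:
                alpha = 0.5 + (seg_end - t) / (2 * tr)
                img = alpha * img + (1 - alpha) * _render_class(spec, next_cls, t, model)

    frame_index = int(np.floor(t * spec.fps + 1e-9))
    noise_rng = np.random.default_rng([spec.seed, 202, frame_index])
    img = img + spec.noise_sd * noise_rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


def render_video(
    spec: ScenarioSpec,
    out: str | Path,
    model: AppearanceModel | None = None,
) -> tuple[Path, AnnotationTrack]:
    """Render every frame of the scenario to ``out`` and return the truth track."""
    timestamps = np.arange(spec.n_frames) / spec.fps
    frames = np.stack([render_frame(spec, float(t), model) for t in timestamps])
    path = write_video(out, frames, spec.fps)
    return path, spec.track()


def frame_provider(
    specs: Sequence[ScenarioSpec], model: AppearanceModel | None = None
) -> Callable[[str, Sequence[float]], np.ndarray]:
    """On-the-fly frame source keyed by video id, for streaming pipelines.

    Returns ``provider(video_id, timestamps) -> (n, H, W, 3)`` so training
    and evaluation can sample frames at 1 fps without materializing full
    videos on disk.
    """
    by_id = {s.video_id: s for s in specs}

    def provider(video_id: str, timestamps: Sequence[float]) -> np.ndarray:
        spec = by_id[video_id]
        return np.stack([render_frame(spec, float(t), model) for t in timestamps])

    return provider


def separability_labels(frame: np.ndarray) -> str:
    """Trivial mean-channel oracle: red-dominant → inside, else outside."""
    return "INSIDE" if float(frame[..., 0].mean() - frame[..., 2].mean()) > 0.0 else "OUTSIDE"
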