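import numpy as np
import pytest

from ioda.annotation import AnnotationInterval, AnnotationTrack, FrameClass
from ioda.synthetic import ScenarioSpec, render_video


@pytest.fixture
def two_interval_track() -> AnnotationTrack:
    return AnnotationTrack(
        "vid-a",
        12.0,
        25.0,
        [
            AnnotationInterval(0.0, 10.0, FrameClass.ABDOMINAL_CAVITY),
            AnnotationInterval(10.0, 12.0, FrameClass.OUTSIDE),
        ],
    ).normalize()


def random_track(rng: np.random.Generator, n_intervals: int, video_id: str = "rand") -> AnnotationTrack:
    """Seeded random valid track with the requested number of intervals."""
    bounds = np.cumsum(rng.uniform(0.2, 30.0, size=n_intervals))
    labels = [list(FrameClass)[i] for i in rng.integers(0, 5, size=n_intervals)]
    intervals, start = [], 0.0
    for end, label in zip(bounds, labels):
        intervals.append(AnnotationInterval(start, float(end), FrameClass(label)))
        start = float(end)
    return AnnotationTrack(video_id, float(bounds[-1]), 25.0, intervals).normalize()


@pytest.fixture(scope="session")
def fixture_spec() -> ScenarioSpec:
    """60 s inside/outside video at desk scale: [0,40) cavity, [40,60) outside."""
    return ScenarioSpec(
        video_id="fixture-60s",
        fps=5.0,
        width=160,
        height=90,
        segments=[(FrameClass.ABDOMINAL_CAVITY, 40.0), (FrameClass.OUTSIDE, 20.0)],
        seed=7,
    )


@pytest.fixture(scope="session")
def rendered_fixture(fixture_spec, tmp_path_factory):
    """(video path, truth track) for the 60 s two-segment scenario."""
    out = tmp_path_factory.mktemp("video") / "fixture-60s.tiff"
    path, track = render_video(fixture_spec, out)
    return path, track
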