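"""Timeline smoothing, label expansion and frame censoring."""

import json

import numpy as np
import pytest

from ioda.annotation import BinaryClass
from ioda.redaction import (
    LabelTimeline,
    RedactionPolicy,
    censored_ranges,
    expand,
    redact,
    smooth,
)
from ioda.video_io import read_video

I, O = BinaryClass.INSIDE, BinaryClass.OUTSIDE


def tl(tokens: str, rate: float = 1.0) -> LabelTimeline:
    return LabelTimeline(rate, [I if c == "I" else O for c in tokens])


def brute_force_smooth(timeline: LabelTimeline, policy: RedactionPolicy) -> list[BinaryClass]:
    """Independent fixpoint simulator: rescan runs until nothing changes."""
    labels = list(timeline.labels)
    min_frames = policy.min_island_s * timeline.sample_rate
    while True:
        runs = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] is not labels[start]:
                runs.append((start, i, labels[start]))
                start = i
        changed = False
        for r in range(1, len(runs) - 1):
            s, e, lab = runs[r]
            if e - s < min_frames and runs[r - 1][2] is runs[r + 1][2]:
                if policy.smoothing == "privacy_safe" and lab is O:
                    continue
                labels[s:e] = [runs[r - 1][2]] * (e - s)
                changed = True
                break
        if not changed:
            return labels


class TestSmooth:
    def test_short_inside_island_absorbed_symmetric(self):
        out = smooth(tl("IIOII"), RedactionPolicy(smoothing="symmetric"))
        assert out.labels == [I] * 5

    def test_privacy_safe_never_flips_outside_to_inside(self):
        out = smooth(tl("IIOII"), RedactionPolicy(smoothing="privacy_safe"))
        assert out.labels == tl("IIOII").labels

    def test_privacy_safe_still_removes_inside_islands(self):
        out = smooth(tl("OOIOO"), RedactionPolicy(smoothing="privacy_safe"))
        assert out.labels == [O] * 5

    def test_edge_runs_never_reassigned(self):
        # the single leading O has no left neighbor, so it stays
        out = smooth(tl("OIIII"), RedactionPolicy(smoothing="symmetric"))
        assert out.labels == tl("OIIII").labels

    def test_smoothing_off_is_identity(self):
        t = tl("IOIOIO")
        assert smooth(t, RedactionPolicy(smoothing="off")).labels == t.labels

    def test_iterates_to_fixpoint(self):
        # flipping the middle O island merges I-runs and exposes nothing new;
        # a cascading case: I O I O I with min 2 → all inside (symmetric)
        out = smooth(tl("IIOIOII"), RedactionPolicy(smoothing="symmetric"))
        assert out.labels == [I] * 7

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("smoothing", ["symmetric", "privacy_safe"])
    def test_matches_brute_force_fixpoint_simulator(self, seed, smoothing):
        rng = np.random.default_rng(seed)
        tokens = "".join("IO"[i] for i in rng.integers(0, 2, 60))
        policy = RedactionPolicy(smoothing=smoothing, min_island_s=float(rng.integers(1, 4)))
        ours = smooth(tl(tokens), policy)
        assert ours.labels == brute_force_smooth(tl(tokens), policy)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_increases_label_switches(self, seed):
        rng = np.random.default_rng(seed)
        tokens = "".join("IO"[i] for i in rng.integers(0, 2, 80))
        t = tl(tokens)
        assert smooth(t, RedactionPolicy(smoothing="symmetric")).n_switches() <= t.n_switches()

    @pytest.mark.parametrize("seed", range(5))
    def test_privacy_safe_never_decreases_outside_frames(self, seed):
        rng = np.random.default_rng(seed)
        tokens = "".join("IO"[i] for i in rng.integers(0, 2, 80))
        t = tl(tokens)
        before = sum(1 for l in t.labels if l is O)
        after = sum(1 for l in smooth(t, RedactionPolicy(smoothing="privacy_safe")).labels if l is O)
        assert after >= before


class TestExpand:
    def test_each_second_covers_its_native_frames(self):
        out = expand(tl("IOI"), native_fps=25.0, frame_count=75)
        assert out[:25] == [I] * 25
        assert out[25:50] == [O] * 25
        assert out[50:] == [I] * 25

    def test_trailing_frame_inherits_last_label(self):
        out = expand(tl("IOI"), native_fps=25.0, frame_count=76)
        assert out[75] is I

    def test_empty_timeline_rejected(self):
        with pytest.raises(ValueError):
            expand(LabelTimeline(1.0, []), 25.0, 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_frame_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        tokens = "".join("IO"[i] for i in rng.integers(0, 2, 40))
        fps = float(rng.choice([5.0, 24.0, 25.0, 30.0]))
        n = int(40 * fps) + int(rng.integers(0, 2))
        ours = expand(tl(tokens), fps, n)
        timeline = tl(tokens)
        brute = [
            timeline.labels[min(int(i / fps * 1.0 + 1e-9), len(timeline.labels) - 1)]
            for i in range(n)
        ]
        assert ours == brute


class TestRedact:
    def test_all_inside_censors_nothing(self, rendered_fixture, tmp_path):
        path, _ = rendered_fixture
        n = len(read_video(path))
        out, manifest = redact(path, [I] * n, out=tmp_path / "anon.tiff", fps=5.0)
        assert manifest.censored_frames == 0
        assert manifest.censored_ranges == []

    def test_all_outside_black_frames(self, rendered_fixture, tmp_path):
        path, _ = rendered_fixture
        n = len(read_video(path))
        out, manifest = redact(path, [O] * n, out=tmp_path / "anon.tiff", fps=5.0)
        frames = read_video(out)
        assert frames.mean() == 0.0
        assert manifest.censored_frames == n

    def test_fixture_ground_truth_labels_censor_frames_200_to_300(self, rendered_fixture, tmp_path):
        # 60 s at 5 fps with [0,40) inside, [40,60) outside
        path, track = rendered_fixture
        labels = [I] * 200 + [O] * 100
        out, manifest = redact(path, labels, out=tmp_path / "anon.tiff", fps=5.0)
        assert manifest.censored_ranges == [(200, 300)]
        frames = read_video(out)
        assert frames[200:].max() == 0.0
        assert frames[:200].mean() > 0.0

    def test_manifest_json_contents(self, rendered_fixture, tmp_path):
        path, _ = rendered_fixture
        out, manifest = redact(path, [I] * 150 + [O] * 150, out=tmp_path / "anon.tiff", fps=5.0)
        doc = json.loads((tmp_path / "anon.manifest.json").read_text())
        assert doc["censored_ranges"] == [[150, 300]]
        assert doc["censored_frames"] == 150
        assert doc["frame_count"] == 300

    def test_label_count_mismatch_is_hard_error_without_output(self, rendered_fixture, tmp_path):
        path, _ = rendered_fixture
        target = tmp_path / "anon.tiff"
        with pytest.raises(ValueError, match="refusing"):
            redact(path, [O] * 10, out=target, fps=5.0)
        assert not target.exists()

    def test_no_outside_frame_survives_uncensored(self, rendered_fixture, tmp_path):
        path, _ = rendered_fixture
        rng = np.random.default_rng(0)
        labels = [O if b else I for b in rng.integers(0, 2, 300)]
        out, manifest = redact(path, labels, out=tmp_path / "anon.tiff", fps=5.0)
        frames = read_video(out)
        for i, label in enumerate(labels):
            if label is O:
                assert frames[i].max() == 0.0

    @pytest.mark.parametrize("mode", ["black", "blur"])
    def test_redaction_is_idempotent(self, rendered_fixture, tmp_path, mode):
        path, _ = rendered_fixture
        labels = [I] * 150 + [O] * 150
        policy = RedactionPolicy(mode=mode)
        once, _ = redact(path, labels, policy, out=tmp_path / "anon1.tiff", fps=5.0)
        twice, _ = redact(once, labels, policy, out=tmp_path / "anon2.tiff", fps=5.0)
        a, b = read_video(once), read_video(twice)
        assert np.array_equal(a[150:], b[150:])

    def test_blur_kernel_is_at_least_an_eighth_of_frame_width(self, rendered_fixture, tmp_path):
        path, _ = rendered_fixture
        out, _ = redact(
            path, [O] * 300, RedactionPolicy(mode="blur"), out=tmp_path / "anon.tiff", fps=5.0
        )
        frame = read_video(out)[250]
        block = frame.shape[1] // 8
        patch = frame[:block, :block]
        assert patch.std(axis=(0, 1)).max() < 1e-6  # block-constant


class TestCensoredRanges:
    def test_half_open_ranges(self):
        labels = [I, O, O, I, O]
        assert censored_ranges(labels) == [(1, 3), (4, 5)]
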