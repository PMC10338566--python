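"""Class taxonomy, interval-track invariants and the annotation CSV format."""

import numpy as np
import pytest

from ioda.annotation import (
    AnnotationError,
    AnnotationInterval,
    AnnotationTrack,
    BinaryClass,
    FrameClass,
    VideoRecord,
    class_distribution,
    load_track,
    save_track,
    to_binary,
)
from tests.conftest import random_track


class TestBinaryMapping:
    def test_mapping_is_total_and_surjective(self):
        images = {to_binary(c) for c in FrameClass}
        assert images == set(BinaryClass)

    @pytest.mark.parametrize(
        "label,expected",
        [
            (FrameClass.ABDOMINAL_CAVITY, BinaryClass.INSIDE),
            (FrameClass.TROCAR, BinaryClass.INSIDE),
            (FrameClass.OUTSIDE, BinaryClass.OUTSIDE),
            (FrameClass.CLEANING, BinaryClass.OUTSIDE),
            (FrameClass.TRANSLUCENT_TROCAR, BinaryClass.OUTSIDE),
        ],
    )
    def test_fixed_mapping(self, label, expected):
        assert to_binary(label) is expected


class TestTrackValidation:
    def test_overlap_is_rejected_naming_the_pair(self):
        track = AnnotationTrack(
            "v",
            12.0,
            25.0,
            [
                AnnotationInterval(0, 10, FrameClass.ABDOMINAL_CAVITY),
                AnnotationInterval(9, 12, FrameClass.OUTSIDE),
            ],
        )
        with pytest.raises(AnnotationError, match="overlap.*t=9"):
            track.validate()

    def test_gap_is_rejected_with_uncovered_span(self):
        track = AnnotationTrack(
            "v",
            12.0,
            25.0,
            [
                AnnotationInterval(0, 5, FrameClass.OUTSIDE),
                AnnotationInterval(7, 12, FrameClass.OUTSIDE),
            ],
        )
        with pytest.raises(AnnotationError, match=r"gap.*\[5.*7"):
            track.validate()

    def test_equal_label_neighbors_merge(self):
        track = AnnotationTrack(
            "v",
            12.0,
            25.0,
            [
                AnnotationInterval(0, 5, FrameClass.OUTSIDE),
                AnnotationInterval(5, 12, FrameClass.OUTSIDE),
            ],
        ).normalize()
        assert len(track.intervals) == 1
        assert (track.intervals[0].start_s, track.intervals[0].end_s) == (0.0, 12.0)

    def test_normalization_is_idempotent(self):
        rng = np.random.default_rng(5)
        track = random_track(rng, 50)
        once = track.normalize()
        twice = once.normalize()
        assert once.intervals == twice.intervals

    def test_empty_track_of_zero_duration_is_valid(self):
        AnnotationTrack("v", 0.0, 25.0, []).validate()


class TestClassAt:
    def test_half_open_boundary_belongs_to_next_interval(self, two_interval_track):
        assert two_interval_track.class_at(10.0) is FrameClass.OUTSIDE
        assert two_interval_track.class_at(9.999) is FrameClass.ABDOMINAL_CAVITY

    def test_out_of_range_raises(self, two_interval_track):
        with pytest.raises(AnnotationError):
            two_interval_track.class_at(12.0)
        with pytest.raises(AnnotationError):
            two_interval_track.class_at(-0.1)


class TestCsvRoundTrip:
    def test_parse_two_intervals(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "video_id,start_s,end_s,label\n"
            "v,0,10,ABDOMINAL_CAVITY\n"
            "v,10,12,OUTSIDE\n"
        )
        track = load_track(p, duration_s=12.0)
        assert len(track.intervals) == 2
        assert track.intervals[1].label is FrameClass.OUTSIDE

    def test_unknown_token_is_hard_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("video_id,start_s,end_s,label\nv,0,10,INSIDE_THE_BODY\n")
        with pytest.raises(AnnotationError, match="INSIDE_THE_BODY"):
            load_track(p)

    def test_round_trip_identity(self, two_interval_track, tmp_path):
        p = tmp_path / "t.csv"
        save_track(two_interval_track, p)
        back = load_track(p, duration_s=two_interval_track.duration_s)
        assert back.intervals == two_interval_track.intervals
        assert back.video_id == two_interval_track.video_id

    def test_empty_track_round_trip(self, tmp_path):
        p = tmp_path / "t.csv"
        save_track(AnnotationTrack("v", 0.0, 25.0, []), p)
        back = load_track(p, duration_s=0.0)
        assert back.intervals == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_of_seeded_random_tracks(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        track = random_track(rng, 1000)
        p = tmp_path / "t.csv"
        save_track(track, p)
        back = load_track(p, duration_s=track.duration_s)
        assert back.intervals == track.intervals


class TestClassDistribution:
    def test_reference_frame_counts_give_reported_shares(self):
        # frame counts of the five classes in a large annotated corpus
        counts = {
            FrameClass.ABDOMINAL_CAVITY: 15_134_978,
            FrameClass.TROCAR: 257_988,
            FrameClass.OUTSIDE: 2_988_220,
            FrameClass.CLEANING: 201_282,
            FrameClass.TRANSLUCENT_TROCAR: 12_788,
        }
        fps = 25.0
        intervals, start = [], 0.0
        for label, n in counts.items():
            intervals.append(AnnotationInterval(start, start + n / fps, label))
            start += n / fps
        track = AnnotationTrack("corpus", start, fps, intervals)
        dist = class_distribution([track])
        for label, n in counts.items():
            assert dist[label][0] == n
        shares = {label: round(100 * frac, 2) for label, (_, frac) in dist.items()}
        assert shares[FrameClass.ABDOMINAL_CAVITY] == 81.39
        assert shares[FrameClass.TROCAR] == 1.39
        assert shares[FrameClass.OUTSIDE] == 16.07
        assert shares[FrameClass.CLEANING] == 1.08
        assert shares[FrameClass.TRANSLUCENT_TROCAR] == 0.07

    def test_single_class_track(self):
        track = AnnotationTrack(
            "v", 10.0, 25.0, [AnnotationInterval(0, 10, FrameClass.OUTSIDE)]
        )
        dist = class_distribution([track], fps=25.0)
        assert dist[FrameClass.OUTSIDE] == (250, 1.0)
        assert dist[FrameClass.ABDOMINAL_CAVITY][0] == 0

    def test_matches_brute_force_per_frame_tally(self):
        rng = np.random.default_rng(11)
        tracks = [random_track(rng, 30, f"v{i}") for i in range(4)]
        dist = class_distribution(tracks, fps=25.0)
        brute = {c: 0 for c in FrameClass}
        for track in tracks:
            n = int(round(track.duration_s * 25.0))
            for i in range(n):
                brute[track.class_at(i / 25.0)] += 1
        for c in FrameClass:
            assert dist[c][0] == brute[c]
        assert sum(f for _, f in dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_counts_conserved_under_binary_collapse(self):
        rng = np.random.default_rng(3)
        tracks = [random_track(rng, 40)]
        dist = class_distribution(tracks, fps=25.0)
        by_binary = {b: 0 for b in BinaryClass}
        for c, (n, _) in dist.items():
            by_binary[to_binary(c)] += n
        total = sum(n for n, _ in dist.values())
        assert sum(by_binary.values()) == total == tracks[0].n_frames(25.0)

    def test_empty_track_list_is_an_error(self):
        with pytest.raises(AnnotationError):
            class_distribution([])


class TestVideoRecord:
    def test_category_is_checked(self):
        with pytest.raises(AnnotationError, match="category"):
            VideoRecord("v", "orthopedic", "op", 60.0, 25.0)

    def test_json_round_trip(self, tmp_path):
        rec = VideoRecord("v", "colorectal", "sigmoid_resection", 3600.0, 25.0)
        p = tmp_path / "rec.json"
        rec.to_json(p)
        assert VideoRecord.from_json(p) == rec
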