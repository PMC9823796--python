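"""Dialect parser tests: parse fidelity on handcrafted fixtures, the stated
tie/offset rules, skeleton mapping and lossless standard-file round trips."""

import json

import numpy as np
import pytest

from pose2grf import keypoint_io as kio
from pose2grf import synthetic


def _coco_triplets(points: dict[int, tuple[float, float, float]]) -> list[float]:
    flat = [0.0] * 51
    for slot, (x, y, c) in points.items():
        flat[3 * slot : 3 * slot + 3] = [x, y, c]
    return flat


class TestOpenPose:
    def _write(self, tmp_path, idx, payload):
        (tmp_path / f"trial_{idx:012d}_keypoints.json").write_text(json.dumps(payload))

    def test_parse_fidelity(self, tmp_path):
        self._write(tmp_path, 0, {"version": 1.3, "people": [
            {"pose_keypoints_2d": _coco_triplets({0: (100.5, 200.25, 0.9)})}]})
        frames = kio.read_openpose_dir(tmp_path)
        assert frames[0].xy[0].tolist() == [100.5, 200.25]
        assert frames[0].confidence[0] == 0.9

    def test_empty_people_gives_absent_frame(self, tmp_path):
        self._write(tmp_path, 0, {"version": 1.3, "people": []})
        frames = kio.read_openpose_dir(tmp_path)
        assert np.all(frames[0].confidence == 0.0)

    def test_noncontiguous_indices_filled(self, tmp_path, caplog):
        # files for frames 0, 2, 3 -> 4 frames with frame 1 all-absent
        for i in (0, 2, 3):
            self._write(tmp_path, i, {"version": 1.3, "people": [
                {"pose_keypoints_2d": _coco_triplets({5: (1.0 + i, 2.0, 0.8)})}]})
        frames = kio.read_openpose_dir(tmp_path)
        assert len(frames) == 4
        assert np.all(frames[1].confidence == 0.0)
        assert frames[2].xy[5, 0] == 3.0

    def test_malformed_json_names_file(self, tmp_path):
        bad = tmp_path / "trial_000000000000_keypoints.json"
        bad.write_text("{not json")
        with pytest.raises(ValueError, match=str(bad)):
            kio.read_openpose_dir(tmp_path)


class TestAlphaPose:
    def test_single_person_exact(self, tmp_path):
        path = tmp_path / "alpha.json"
        path.write_text(json.dumps([
            {"image_id": "0.jpg", "keypoints": _coco_triplets({15: (11.25, 7.5, 0.7)}), "score": 1.0}]))
        frames = kio.read_alphapose_json(path)
        assert frames[0].xy[15].tolist() == [11.25, 7.5]

    def test_highest_score_person_kept(self, tmp_path):
        path = tmp_path / "alpha.json"
        path.write_text(json.dumps([
            {"image_id": "0.jpg", "keypoints": _coco_triplets({5: (1.0, 1.0, 0.9)}), "score": 0.4},
            {"image_id": "0.jpg", "keypoints": _coco_triplets({5: (2.0, 2.0, 0.9)}), "score": 0.9},
        ]))
        frames = kio.read_alphapose_json(path)
        assert frames[0].xy[5, 0] == 2.0

    def test_equal_scores_keep_lower_index_with_warning(self, tmp_path, caplog):
        path = tmp_path / "alpha.json"
        path.write_text(json.dumps([
            {"image_id": "0.jpg", "keypoints": _coco_triplets({5: (1.0, 1.0, 0.9)}), "score": 0.5},
            {"image_id": "0.jpg", "keypoints": _coco_triplets({5: (2.0, 2.0, 0.9)}), "score": 0.5},
        ]))
        with caplog.at_level("WARNING"):
            frames = kio.read_alphapose_json(path)
        assert frames[0].xy[5, 0] == 1.0
        assert any("equal detection scores" in m for m in caplog.messages)


class TestBlazePose:
    def _records(self, n):
        recs = []
        for k in range(n):
            lms = [{"x": 0.0, "y": 0.0, "visibility": 0.0}] * 33
            lms = [dict(lm) for lm in lms]
            lms[27] = {"x": 0.5, "y": 0.5, "visibility": 0.9}
            recs.append({"frame_index": k, "landmarks": lms})
        return recs

    def test_rescale_to_pixels(self, tmp_path):
        path = tmp_path / "blaze.json"
        path.write_text(json.dumps(self._records(3)))
        frames = kio.read_blazepose_frames(path, image_width=1920, image_height=1080)
        assert frames[0].xy[27].tolist() == [960.0, 540.0]

    def test_offset_correction_drops_one_frame(self, tmp_path):
        path = tmp_path / "blaze.json"
        path.write_text(json.dumps(self._records(100)))
        frames = kio.read_blazepose_frames(path, image_width=100, image_height=100)
        assert len(frames) == 99

    def test_offset_correction_realigns_content(self, tmp_path):
        # record k describes video frame k-1: encode the source frame number
        # in the x coordinate and check alignment after correction
        recs = []
        for k in range(5):
            lms = [{"x": 0.0, "y": 0.0, "visibility": 0.0} for _ in range(33)]
            content_frame = max(0, k - 1)
            lms[27] = {"x": content_frame / 100.0, "y": 0.1, "visibility": 0.9}
            recs.append({"frame_index": k, "landmarks": lms})
        path = tmp_path / "blaze.json"
        path.write_text(json.dumps(recs))
        frames = kio.read_blazepose_frames(path, image_width=100, image_height=100)
        for i, f in enumerate(frames):
            assert f.xy[27, 0] == pytest.approx(i)

    def test_missing_dimensions_refused(self, tmp_path):
        path = tmp_path / "blaze.json"
        path.write_text(json.dumps(self._records(2)))
        with pytest.raises(ValueError, match="image dimensions"):
            kio.read_blazepose_frames(path, image_width=0, image_height=1080)


class TestCommonSkeleton:
    def test_coco_map_fidelity(self):
        f = kio.RawKeypointFrame.empty(0, kio.COCO17)
        f.xy[15] = [3.0, 4.0]
        f.confidence[15] = 0.8
        trial = kio.to_common_skeleton([f], kio.COCO17)
        assert trial.presence[0].tolist() == [False] * 6 + [True, False]  # L_ankle only
        assert trial.coords[0, 6].tolist() == [3.0, 4.0]

    def test_zero_confidence_absent_under_default_threshold(self):
        f = kio.RawKeypointFrame.empty(0, kio.COCO17)
        f.xy[5] = [1.0, 2.0]
        f.confidence[5] = 0.0
        trial = kio.to_common_skeleton([f], kio.COCO17)
        assert not trial.presence[0, 0]

    def test_unknown_skeleton_refused(self):
        with pytest.raises(ValueError, match="unknown skeleton"):
            kio.to_common_skeleton([], "BODY25")

    def test_maps_injective_and_total(self):
        for skel, slots in kio.SKELETON_MAPS.items():
            assert len(slots) == 8
            assert len(set(slots)) == 8


class TestRoundTrips:
    """Writer -> reader -> mapper reproduces the synthetic coordinates."""

    @pytest.mark.parametrize("dialect", ["openpose", "alphapose", "blazepose"])
    def test_dialect_round_trip(self, dialect, one_trial, tmp_path):
        _, kp, _, _ = one_trial
        if dialect == "openpose":
            synthetic.write_openpose_dir(kp, tmp_path / "op")
            frames = kio.read_openpose_dir(tmp_path / "op")
            skel = kio.COCO17
        elif dialect == "alphapose":
            synthetic.write_alphapose_json(kp, tmp_path / "ap.json")
            frames = kio.read_alphapose_json(tmp_path / "ap.json")
            skel = kio.COCO17
        else:
            synthetic.write_blazepose_json(kp, tmp_path / "bp.json")
            frames = kio.read_blazepose_frames(
                tmp_path / "bp.json",
                image_width=synthetic.IMAGE_WIDTH,
                image_height=synthetic.IMAGE_HEIGHT,
            )
            skel = kio.BLAZE33
        back = kio.to_common_skeleton(frames, skel, fps=kp.fps)
        assert back.n_frames == kp.n_frames
        np.testing.assert_array_equal(back.presence, kp.presence)
        tol = 1e-9 if dialect != "blazepose" else 1e-9  # normalisation is exact in float64
        np.testing.assert_allclose(back.coords[back.presence], kp.coords[kp.presence], atol=1e-6)

    def test_standard_trial_round_trip(self, one_trial, tmp_path):
        _, kp, _, _ = one_trial
        path = kio.write_standard_trial(kp, tmp_path / "std.json")
        back = kio.read_standard_trial(path)
        np.testing.assert_array_equal(back.coords, kp.coords)
        np.testing.assert_array_equal(back.presence, kp.presence)
        assert back.subject_id == kp.subject_id
        assert back.fps == kp.fps

    def test_unknown_movement_label_refused(self, one_trial, tmp_path):
        _, kp, _, _ = one_trial
        path = kio.write_standard_trial(kp, tmp_path / "std.json")
        payload = json.loads(path.read_text())
        payload["metadata"]["movement"] = "jousting"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="unknown movement"):
            kio.read_standard_trial(path)

    def test_version_mismatch_refused(self, one_trial, tmp_path):
        _, kp, _, _ = one_trial
        path = kio.write_standard_trial(kp, tmp_path / "std.json")
        payload = json.loads(path.read_text())
        payload["schema"] = "pose2grf-trial/99"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="schema version"):
            kio.read_standard_trial(path)

    def test_zero_frame_trial_refused_on_write(self, tmp_path):
        from pose2grf.types import KeypointTrial

        empty = KeypointTrial(
            subject_id="s", movement="running", camera_view="TS", estimator="A",
            fps=25.0, coords=np.zeros((0, 8, 2)), presence=np.zeros((0, 8), dtype=bool),
        )
        with pytest.raises(ValueError, match="0 frames"):
            kio.write_standard_trial(empty, tmp_path / "std.json")
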