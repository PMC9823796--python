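"""Readers and writers for pose-estimator keypoint streams.

Three input dialects are supported:

* **OpenPose-style**: a directory with one JSON file per frame, each holding a
  ``people`` list whose entries carry a flat ``pose_keypoints_2d`` list of
  ``x, y, confidence`` triplets on the COCO 17-keypoint skeleton.
* **AlphaPose-style**: a single JSON file per trial, a list of detections with
  ``image_id``, a 51-value ``keypoints`` triplet list (COCO-17) and a
  detection ``score``. Multiple detections per frame are resolved by keeping
  the highest score (ties: lowest list index, with a warning).
* **BlazePose-style**: per-frame landmark records with coordinates normalised
  to [0, 1] on the 33-landmark skeleton. The stream carries a characteristic
  one-frame offset (record *k* describes video frame *k-1*) which is corrected
  by dropping the first record and shifting the remainder back.

All dialects are mapped onto the common 8-joint analysis skeleton
(bilateral shoulder, hip, knee, ankle) and stored in a standardised per-trial
JSON file with a schema version header.

Parsing never invents coordinates: every present cell in the output maps to a
literal value in an input file.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from pose2grf.types import (
    CAMERA_VIEWS,
    MOVEMENTS,
    N_JOINTS,
    KeypointTrial,
)

logger = logging.getLogger(__name__)

COCO17 = "COCO17"
BLAZE33 = "BLAZE33"

_SKELETON_SIZES = {COCO17: 17, BLAZE33: 33}

#: analysis-joint index -> slot in each source skeleton
#: (order: L/R shoulder, L/R hip, L/R knee, L/R ankle)
SKELETON_MAPS: dict[str, tuple[int, ...]] = {
    COCO17: (5, 6, 11, 12, 13, 14, 15, 16),
    BLAZE33: (11, 12, 23, 24, 25, 26, 27, 28),
}

TRIAL_SCHEMA = "pose2grf-trial/1"


@dataclass
class RawKeypointFrame:
    """One frame of a source-skeleton keypoint stream."""

    frame_index: int
    xy: np.ndarray  # (n_points, 2) px
    confidence: np.ndarray  # (n_points,)
    skeleton: str

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        n = _SKELETON_SIZES.get(self.skeleton)
        if n is None:
            raise ValueError(f"unknown skeleton {self.skeleton!r}")
        if self.xy.shape != (n, 2) or self.confidence.shape != (n,):
            raise ValueError(f"{self.skeleton} frame must carry {n} points")

    @classmethod
    def empty(cls, frame_index: int, skeleton: str) -> "RawKeypointFrame":
        n = _SKELETON_SIZES[skeleton]
        return cls(frame_index, np.zeros((n, 2)), np.zeros(n), skeleton)


def _triplets_to_frame(triplets: list[float], frame_index: int, skeleton: str) -> RawKeypointFrame:
    n = _SKELETON_SIZES[skeleton]
    arr = np.asarray(triplets, dtype=float).reshape(n, 3)
    return RawKeypointFrame(frame_index, arr[:, :2], arr[:, 2], skeleton)


def read_openpose_dir(path: str | Path) -> list[RawKeypointFrame]:
    """Parse a directory of per-frame OpenPose-style JSON files.

    Frame indices are recovered from the zero-padded number in each filename;
    missing indices are filled with all-absent frames (with a warning), and a
    frame whose ``people`` list is empty yields an all-absent frame.
    """
    path = Path(path)
    pattern = re.compile(r"_(\d+)_keypoints\.json$")
    indexed: dict[int, Path] = {}
    for f in sorted(path.glob("*_keypoints.json")):
        m = pattern.search(f.name)
        if m:
            indexed[int(m.group(1))] = f
    if not indexed:
        raise FileNotFoundError(f"no *_keypoints.json files in {path}")
    frames: list[RawKeypointFrame] = []
    max_idx = max(indexed)
    missing = [i for i in range(max_idx + 1) if i not in indexed]
    if missing:
        logger.warning("non-contiguous frame indices in %s; filling %d absent frames", path, len(missing))
    for i in range(max_idx + 1):
        if i not in indexed:
            frames.append(RawKeypointFrame.empty(i, COCO17))
            continue
        try:
            payload = json.loads(indexed[i].read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed JSON in {indexed[i]}: {exc}") from exc
        people = payload.get("people", [])
        if not people:
            frames.append(RawKeypointFrame.empty(i, COCO17))
        else:
            frames.append(_triplets_to_frame(people[0]["pose_keypoints_2d"], i, COCO17))
    return frames


def read_alphapose_json(path: str | Path) -> list[RawKeypointFrame]:
    """Parse a single AlphaPose-style results JSON covering a whole trial."""
    path = Path(path)
    try:
        entries = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON in {path}: {exc}") from exc
    by_frame: dict[int, dict] = {}
    for k, entry in enumerate(entries):
        idx = int(re.match(r"(\d+)", str(entry["image_id"])).group(1))
        score = float(entry.get("score", 0.0))
        prev = by_frame.get(idx)
        if prev is None or score > prev["score"]:
            by_frame[idx] = {"score": score, "keypoints": entry["keypoints"], "order": k}
        elif score == prev["score"]:
            logger.warning(
                "equal detection scores in frame %d of %s; keeping lower person index", idx, path
            )
    if not by_frame:
        return []
    frames = []
    for i in range(max(by_frame) + 1):
        if i in by_frame:
            frames.append(_triplets_to_frame(by_frame[i]["keypoints"], i, COCO17))
        else:
            frames.append(RawKeypointFrame.empty(i, COCO17))
    return frames


def read_blazepose_frames(
    path: str | Path,
    image_width: int,
    image_height: int,
) -> list[RawKeypointFrame]:
    """Parse BlazePose-style per-frame landmark records.

    Coordinates are normalised to [0, 1] and rescaled with the mandatory image
    dimensions. The stream's one-frame offset is corrected by dropping the
    first record, so an n-record stream yields n-1 aligned frames.
    """
    if not image_width or not image_height:
        raise ValueError("image dimensions are required to rescale BlazePose landmarks")
    path = Path(path)
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON in {path}: {exc}") from exc
    records = sorted(records, key=lambda r: int(r["frame_index"]))
    frames: list[RawKeypointFrame] = []
    for out_idx, rec in enumerate(records[1:]):  # drop the spurious first record
        lms = rec["landmarks"]
        if len(lms) != 33:
            raise ValueError(f"BlazePose record {rec['frame_index']} has {len(lms)} landmarks, expected 33")
        xy = np.array([[lm["x"] * image_width, lm["y"] * image_height] for lm in lms])
        conf = np.array([lm.get("visibility", 1.0) for lm in lms])
        frames.append(RawKeypointFrame(out_idx, xy, conf, BLAZE33))
    return frames


def to_common_skeleton(
    frames: list[RawKeypointFrame],
    skeleton: str,
    subject_id: str = "unknown",
    movement: str = "running",
    camera_view: str = "TS",
    estimator: str = "unknown",
    fps: float = 25.0,
    trial_id: str = "trial",
    confidence_threshold: float = 0.0,
) -> KeypointTrial:
    """Map a source-skeleton stream onto the 8-joint analysis skeleton.

    A joint is present iff its source point exists and its confidence is
    strictly above ``confidence_threshold`` (default 0.0, so only hard
    absences count).
    """
    if skeleton not in SKELETON_MAPS:
        raise ValueError(f"unknown skeleton {skeleton!r}")
    if any(f.skeleton != skeleton for f in frames):
        raise ValueError("inconsistent skeletons across frames")
    slots = SKELETON_MAPS[skeleton]
    n = len(frames)
    coords = np.zeros((n, N_JOINTS, 2))
    presence = np.zeros((n, N_JOINTS), dtype=bool)
    for i, f in enumerate(frames):
        coords[i] = f.xy[list(slots)]
        presence[i] = f.confidence[list(slots)] > confidence_threshold
    coords[~presence] = 0.0
    return KeypointTrial(
        subject_id=subject_id,
        movement=movement,
        camera_view=camera_view,
        estimator=estimator,
        fps=fps,
        coords=coords,
        presence=presence,
        trial_id=trial_id,
    )


def write_standard_trial(trial: KeypointTrial, path: str | Path) -> Path:
    """Write the standardised per-trial JSON container (lossless)."""
    if trial.n_frames == 0:
        raise ValueError("refusing to write a trial with 0 frames")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "schema": TRIAL_SCHEMA,
        "metadata": {
            "subject_id": trial.subject_id,
            "trial_id": trial.trial_id,
            "movement": trial.movement,
            "camera_view": trial.camera_view,
            "estimator": trial.estimator,
            "fps": trial.fps,
        },
        "coords": trial.coords.tolist(),
        "presence": trial.presence.astype(int).tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def read_standard_trial(path: str | Path) -> KeypointTrial:
    """Read a standardised per-trial JSON container written by
    :func:`write_standard_trial`."""
    path = Path(path)
    payload = json.loads(path.read_text())
    if payload.get("schema") != TRIAL_SCHEMA:
        raise ValueError(
            f"schema version mismatch in {path}: {payload.get('schema')!r} != {TRIAL_SCHEMA!r}"
        )
    md = payload["metadata"]
    if md["movement"] not in MOVEMENTS:
        raise ValueError(f"unknown movement label {md['movement']!r} in {path}")
    if md["camera_view"] not in CAMERA_VIEWS:
        raise ValueError(f"unknown camera view {md['camera_view']!r} in {path}")
    return KeypointTrial(
        subject_id=md["subject_id"],
        movement=md["movement"],
        camera_view=md["camera_view"],
        estimator=md["estimator"],
        fps=float(md["fps"]),
        coords=np.asarray(payload["coords"], dtype=float),
        presence=np.asarray(payload["presence"], dtype=bool),
        trial_id=md.get("trial_id", "trial"),
    )
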