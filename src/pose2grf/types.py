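"""Core containers shared across the pipeline.

Conventions used throughout the package:

* The analysis skeleton has exactly 8 joints in the fixed order
  ``[L_shoulder, R_shoulder, L_hip, R_hip, L_knee, R_knee, L_ankle, R_ankle]``.
* Keypoint coordinates are image pixels, y increasing downward.
* Force components are ordered ``[ML, AP, vertical]`` (medio-lateral,
  anterior-posterior, vertical).
* Frame indices are 0-based; event frames refer to the video frame grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

#: Fixed joint order of the 8-keypoint analysis skeleton.
JOINT_NAMES: tuple[str, ...] = (
    "L_shoulder",
    "R_shoulder",
    "L_hip",
    "R_hip",
    "L_knee",
    "R_knee",
    "L_ankle",
    "R_ankle",
)

#: Indices of the two hip joints inside :data:`JOINT_NAMES`.
HIP_INDICES: tuple[int, int] = (2, 3)

N_JOINTS = len(JOINT_NAMES)
N_INPUT_CHANNELS = 2 * N_JOINTS  # x and y per joint
N_FORCE_COMPONENTS = 3

MOVEMENTS = ("running", "walking", "sidestepping", "crossover")
CAMERA_VIEWS = ("TS", "AS", "PS")
ESTIMATOR_TAGS = ("A", "O", "B")

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometry of one synthetic participant.

    Parameters
    ----------
    subject_id : str
        Opaque label, unique within a cohort.
    mass : float
        Body mass in kg.
    height : float
        Stature in cm.
    leg_length : float
        Leg length expressed as a fraction of stature.
    seed : int
        Per-subject seed used for trial-level randomness.
    """

    subject_id: str
    mass: float
    height: float
    leg_length: float
    seed: int

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.height <= 0 or not (0 < self.leg_length < 1):
            raise ValueError(f"implausible anthropometry for {self.subject_id!r}")

    @property
    def leg_length_m(self) -> float:
        return self.leg_length * self.height / 100.0


@dataclass(frozen=True)
class TrialSpec:
    """Recording conditions for one trial."""

    movement: str = "running"
    camera_view: str = "TS"
    approach_speed: float = 5.0  # m/s
    stance_duration: float = 0.22  # s
    fps_video: float = 25.0  # Hz
    fs_force: float = 2000.0  # Hz
    duration: float = 4.0  # s, total trial length

    def __post_init__(self) -> None:
        if self.movement not in MOVEMENTS:
            raise ValueError(f"unknown movement {self.movement!r}")
        if self.camera_view not in CAMERA_VIEWS:
            raise ValueError(f"unknown camera view {self.camera_view!r}")
        if self.fps_video <= 0 or self.fs_force <= 0 or self.duration <= 0:
            raise ValueError("sampling rates and duration must be positive")
        if self.movement == "running" and not (0.1 < self.stance_duration < 0.4):
            raise ValueError(
                f"running stance duration {self.stance_duration} s outside (0.1, 0.4)"
            )
        if self.stance_duration <= 0:
            raise ValueError("stance duration must be positive")


@dataclass(frozen=True)
class EventPair:
    """Heel-strike / toe-off events on the video frame grid."""

    heel_strike_frame: int
    toe_off_frame: int
    source: str = "manual"

    def __post_init__(self) -> None:
        if self.toe_off_frame <= self.heel_strike_frame:
            raise ValueError("toe off must come after heel strike")
        if self.heel_strike_frame < 0:
            raise ValueError("events must be non-negative frame indices")


@dataclass
class KeypointTrial:
    """Per-trial keypoint time series on the 8-joint analysis skeleton.

    ``coords`` has shape ``(n_frames, 8, 2)`` in pixels and ``presence`` is the
    matching boolean mask; coordinates are only meaningful where present.
    """

    subject_id: str
    movement: str
    camera_view: str
    estimator: str
    fps: float
    coords: np.ndarray
    presence: np.ndarray
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_JOINTS, 2):
            raise ValueError(f"coords must be (n, {N_JOINTS}, 2), got {self.coords.shape}")
        if self.presence.shape != self.coords.shape[:2]:
            raise ValueError("presence mask shape does not match coords")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.movement not in MOVEMENTS:
            raise ValueError(f"unknown movement {self.movement!r}")
        if not np.all(np.isfinite(self.coords[self.presence])):
            raise ValueError("non-finite coordinates at present cells")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "KeypointTrial":
        return replace(self, coords=self.coords.copy(), presence=self.presence.copy())


@dataclass
class ForceTrial:
    """Force-plate record: ``F`` is ``(n_samples, 3)`` N in [ML, AP, vertical] order."""

    fs: float
    F: np.ndarray
    mass: float
    stance: Optional[Tuple[int, int]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2 or self.F.shape[1] != N_FORCE_COMPONENTS:
            raise ValueError(f"F must be (n, 3), got {self.F.shape}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @property
    def n_samples(self) -> int:
        return self.F.shape[0]

    @property
    def vertical(self) -> np.ndarray:
        return self.F[:, 2]


@dataclass
class WindowedTrial:
    """A keypoint trial restricted to stance plus lead-in/lead-out frames.

    ``stance_slice`` indexes the stance sub-range in window coordinates
    (inclusive start, inclusive stop). The validity flags implement the
    completeness rule: a gap touching the first or last window frame cannot be
    interpolated, which invalidates the full window; the analogous rule on the
    stance sub-window governs ``valid_stance``.
    """

    trial: KeypointTrial
    lead_in: int
    lead_out: int
    stance_start: int  # window-frame index of heel strike
    stance_stop: int  # window-frame index of toe off (inclusive)
    valid_full_window: bool = True
    valid_stance: bool = True
    interpolated: bool = False

    @property
    def n_frames(self) -> int:
        return self.trial.n_frames

    @property
    def coords(self) -> np.ndarray:
        return self.trial.coords

    @property
    def presence(self) -> np.ndarray:
        return self.trial.presence


@dataclass
class NormalizedSample:
    """One stance phase, ready for the network.

    ``inputs`` is ``(101, 16)``: hip-centred pixel coordinates, joint-major
    with x before y per joint, on the 101-point normalised-time grid.
    ``targets`` is ``(101, 3)`` mass-normalised GRF in N/kg, [ML, AP, vertical].
    """

    subject_id: str
    trial_id: str
    estimator: str
    inputs: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.shape != (101, N_INPUT_CHANNELS):
            raise ValueError(
                f"inputs must be (101, {N_INPUT_CHANNELS}), got {self.inputs.shape}"
            )
        if self.targets.shape != (101, N_FORCE_COMPONENTS):
            raise ValueError(f"targets must be (101, 3), got {self.targets.shape}")
        if not (np.all(np.isfinite(self.inputs)) and np.all(np.isfinite(self.targets))):
            raise ValueError("normalized sample contains non-finite values")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.trial_id, self.estimator)
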