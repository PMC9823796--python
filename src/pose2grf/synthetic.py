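"""Synthetic gait generator.

Emulates the study conditions the pipeline was designed for: a cohort of
female team-sport athletes (mass 62.77 +/- 5.41 kg, stature 168 +/- 4 cm)
running over a force plate at 4.5-5.5 m/s, filmed sagittally at 25 FPS while
a force plate records the three GRF components at 2000 Hz.

The kinematic model is a sum of sinusoids driven by a stride phase whose
period follows from approach speed and leg length, projected to a sagittal
pixel frame (1 m = 400 px); the camera is treated as subject-tracking, so
residual image-plane drift is small and frame-to-frame displacements stay
bounded. The vertical GRF is the sum of an early impact lobe and an active
half-sine lobe; the anterior-posterior component is a braking-then-propulsion
full-period sine with a mid-stance zero crossing; the medio-lateral component
is a low-amplitude sine with randomised phase and sign, deliberately carrying
little information recoverable from the sagittal keypoints.

Coupling that makes estimator interchangeability measurable: the trial-level
vertical peak factor increases linearly with the apparent stance-leg extent
(hip-to-ankle pixel distance). Three emulated estimator variants observe the
same trajectory: tag ``A`` (reference) and tag ``O`` add independent zero-mean
pixel noise, while tag ``B`` follows a different joint-centre convention that
shifts knee and ankle toward the hip by a fixed fraction of leg length. The
A-O pair is therefore interchangeable to within noise, while B's systematic
offset propagates into a systematic force underestimation for models trained
on A or O — the pattern the interchangeability experiments probe.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from pose2grf.types import (
    ESTIMATOR_TAGS,
    GRAVITY,
    HIP_INDICES,
    N_JOINTS,
    EventPair,
    ForceTrial,
    KeypointTrial,
    SubjectProfile,
    TrialSpec,
)

#: Pixel scale of the synthetic sagittal camera (1 m at the subject plane).
PX_PER_M = 400.0

#: Image geometry the BlazePose-dialect writer normalises against.
IMAGE_WIDTH = 1920
IMAGE_HEIGHT = 1080

#: Reference apparent stance-leg extent (px) at default anthropometry.
_EXTENT_FRAC = 0.92
_DEFAULT_LEG_PX = 0.53 * 1.68 * PX_PER_M
EXTENT_REF_PX = _EXTENT_FRAC * _DEFAULT_LEG_PX

#: Vertical peak factor (bodyweights) gained per pixel of apparent leg extent.
PEAK_PER_EXTENT_PX = 0.014

#: Default per-estimator keypoint noise (px) and joint-convention offset.
SIGMA_NOISE_PX = 2.0
B_OFFSET_FRAC = 0.04

#: Default dropout rates per estimator tag: (interior, boundary).
#: Boundary rates follow from P(valid full window) = (1-p)^16 matched to the
#: detection-rate levels the emulation targets (~98.4 / 94.5 / 65.2 %).
DEFAULT_MISSINGNESS = {
    "A": (0.002, 0.001),
    "O": (0.004, 0.0035),
    "B": (0.02, 0.027),
}


def generate_cohort(
    n_subjects: int,
    seed: int,
    mass_mean: float = 62.77,
    mass_sd: float = 5.41,
    mass_min: float = 40.0,
    height_mean: float = 168.0,
    height_sd: float = 4.0,
    leg_length_frac: float = 0.53,
    leg_length_sd: float = 0.008,
) -> list[SubjectProfile]:
    """Draw ``n_subjects`` anthropometric profiles.

    Mass follows a normal law truncated below ``mass_min``; stature is normal.
    The same ``seed`` always yields the same cohort.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for leave-one-subject-out folds")
    rng = np.random.default_rng(seed)
    a = (mass_min - mass_mean) / mass_sd
    masses = stats.truncnorm.rvs(
        a, np.inf, loc=mass_mean, scale=mass_sd, size=n_subjects, random_state=rng
    )
    heights = rng.normal(height_mean, height_sd, size=n_subjects)
    legs = np.clip(rng.normal(leg_length_frac, leg_length_sd, size=n_subjects), 0.45, 0.60)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    return [
        SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            mass=float(masses[i]),
            height=float(heights[i]),
            leg_length=float(legs[i]),
            seed=int(sub_seeds[i]),
        )
        for i in range(n_subjects)
    ]


def default_trial_spec(rng: np.random.Generator, movement: str = "running") -> TrialSpec:
    """Draw per-trial recording conditions at the study defaults."""
    speed = float(rng.uniform(4.5, 5.5)) if movement != "walking" else float(rng.uniform(1.2, 1.6))
    stance = float(np.clip(rng.normal(0.22, 0.015), 0.18, 0.26))
    if movement == "walking":
        stance = float(np.clip(rng.normal(0.62, 0.04), 0.5, 0.75))
    return TrialSpec(movement=movement, approach_speed=speed, stance_duration=stance)


def _movement_peak_factor(movement: str) -> tuple[float, float, float]:
    """(mean, lo, hi) of the vertical peak factor in bodyweights."""
    if movement == "walking":
        return 1.15, 1.0, 1.4
    return 2.5, 2.0, 3.0


def generate_trial(
    subject: SubjectProfile,
    spec: TrialSpec,
    seed: int,
) -> tuple[KeypointTrial, ForceTrial, EventPair]:
    """Generate one noise-free trial: keypoints, force record and events.

    The keypoint stream covers the whole trial at ``spec.fps_video``; the force
    record is exactly zero outside the stance interval implied by the events
    and its vertical peak equals ``peak_factor * mass * g`` by construction,
    with ``peak_factor`` coupled to the apparent stance-leg extent.
    """
    rng = np.random.default_rng([seed, subject.seed])
    fps = spec.fps_video
    n_frames = int(round(spec.duration * fps))

    # --- events on the video grid ---------------------------------------
    hs_time = spec.duration * 0.45 + rng.uniform(-0.08, 0.08)
    hs_frame = int(round(hs_time * fps))
    stance_frames = max(2, int(round(spec.stance_duration * fps)))
    to_frame = hs_frame + stance_frames
    if to_frame >= n_frames:
        raise ValueError("stance window longer than trial")
    events = EventPair(heel_strike_frame=hs_frame, toe_off_frame=to_frame)
    t_on = hs_frame / fps
    t_off = to_frame / fps
    stance_T = t_off - t_on

    # --- kinematics ------------------------------------------------------
    leg_px = subject.leg_length_m * PX_PER_M
    torso_px = 0.30 * (subject.height / 100.0) * PX_PER_M
    posture = float(np.clip(rng.normal(1.0, 0.03), 0.90, 1.10))
    extent_px = _EXTENT_FRAC * leg_px * posture  # mean hip-to-ankle drop

    # full gait-cycle length; ~3.6 m at 5 m/s gives a realistic ~168 steps/min
    stride_len = (4.2 if spec.movement != "walking" else 1.7) * subject.leg_length_m
    f_stride = spec.approach_speed / stride_len
    t = np.arange(n_frames) / fps
    # heel strike is a stride-phase event: lock phase 0 to stance onset,
    # with a small trial-to-trial timing jitter
    phi0 = rng.normal(0.0, 0.15)
    phi = 2 * np.pi * f_stride * (t - t_on) + phi0

    cx, cy = IMAGE_WIDTH / 2.0, IMAGE_HEIGHT / 2.0
    drift = rng.uniform(-35.0, 35.0)  # px/s residual pan error
    hip_x = cx + drift * (t - t.mean())
    hip_y = cy + 12.0 * np.sin(2 * phi)

    coords = np.zeros((n_frames, N_JOINTS, 2))
    # harmonic phase offsets: anatomy-fixed values plus trial jitter
    psi1 = 0.9 + rng.normal(0.0, 0.1)
    psi2 = 2.2 + rng.normal(0.0, 0.1)

    def put(j: int, x: np.ndarray, y: np.ndarray) -> None:
        coords[:, j, 0] = x
        coords[:, j, 1] = y

    # shoulders: above the hip, counter-phase arm swing
    put(0, hip_x + 10.0 + 15.0 * np.sin(phi + np.pi), hip_y - torso_px + 6.0 * np.sin(2 * phi + psi1))
    put(1, hip_x - 10.0 + 15.0 * np.sin(phi), hip_y - torso_px + 6.0 * np.sin(2 * phi + psi1))
    # hips: small sagittal-plane separation
    put(2, hip_x + 9.0 + 4.0 * np.sin(phi), hip_y)
    put(3, hip_x - 9.0 - 4.0 * np.sin(phi), hip_y)
    # knees
    knee_drop = 0.50 * leg_px * posture
    put(4, hip_x + 0.11 * leg_px * np.sin(phi), hip_y + knee_drop + 18.0 * np.sin(2 * phi + psi2))
    put(5, hip_x + 0.11 * leg_px * np.sin(phi + np.pi), hip_y + knee_drop + 18.0 * np.sin(2 * phi + np.pi + psi2))
    # ankles: the largest excursions; mean drop carries the extent signal
    put(6, hip_x + 0.15 * leg_px * np.sin(phi - 0.4), hip_y + extent_px + 18.0 * np.sin(2 * phi + psi2 + 0.7))
    put(7, hip_x + 0.15 * leg_px * np.sin(phi + np.pi - 0.4), hip_y + extent_px + 18.0 * np.sin(2 * phi + np.pi + psi2 + 0.7))

    kp = KeypointTrial(
        subject_id=subject.subject_id,
        movement=spec.movement,
        camera_view=spec.camera_view,
        estimator="clean",
        fps=fps,
        coords=coords,
        presence=np.ones((n_frames, N_JOINTS), dtype=bool),
        trial_id=f"{subject.subject_id}-t{seed}",
    )

    # --- ground reaction force -------------------------------------------
    pk_mean, pk_lo, pk_hi = _movement_peak_factor(spec.movement)
    peak_factor = float(
        np.clip(
            pk_mean
            + PEAK_PER_EXTENT_PX * (extent_px - EXTENT_REF_PX)
            + rng.normal(0.0, 0.10),
            pk_lo,
            pk_hi,
        )
    )
    a_imp = float(np.clip(rng.normal(0.36, 0.03), 0.2, 0.5))
    s_imp = float(np.clip(rng.normal(0.26, 0.02), 0.18, 0.34))
    ap_amp = float(np.clip(rng.normal(0.25, 0.02), 0.15, 0.35)) * subject.mass * GRAVITY
    ml_amp = float(rng.uniform(0.02, 0.06)) * subject.mass * GRAVITY
    ml_phase = rng.uniform(0, 2 * np.pi)
    ml_sign = rng.choice([-1.0, 1.0])

    n_force = int(round(spec.duration * spec.fs_force))
    tf = np.arange(n_force) / spec.fs_force
    F = np.zeros((n_force, 3))
    in_stance = (tf >= t_on) & (tf <= t_off)
    s = (tf[in_stance] - t_on) / stance_T

    scale = peak_factor * subject.mass * GRAVITY  # shape max is 1 (active lobe)
    vert = np.sin(np.pi * s)
    impact = np.where(s < s_imp, a_imp * np.sin(np.pi * np.clip(s, 0, s_imp) / s_imp), 0.0)
    F[in_stance, 2] = scale * (vert + impact)
    F[in_stance, 1] = -ap_amp * np.sin(2 * np.pi * s)
    F[in_stance, 0] = ml_sign * ml_amp * np.sin(2 * np.pi * s + ml_phase) * np.sin(np.pi * s)

    impulse_target = scale * (2 * stance_T / np.pi + a_imp * 2 * s_imp * stance_T / np.pi)
    force = ForceTrial(
        fs=spec.fs_force,
        F=F,
        mass=subject.mass,
        meta={
            "peak_factor": peak_factor,
            "vertical_impulse_target": float(impulse_target),
            "stance_time": (t_on, t_off),
        },
    )
    return kp, force, events


def apply_estimator(
    trial: KeypointTrial,
    tag: str,
    seed: int,
    sigma_px: float = SIGMA_NOISE_PX,
    offset_frac: float = B_OFFSET_FRAC,
) -> KeypointTrial:
    """Corrupt a clean trial the way one of the emulated estimators would.

    ``A`` and ``O`` add independent zero-mean Gaussian pixel noise; ``B``
    additionally shifts knee and ankle toward the hip by ``offset_frac`` of
    the apparent leg length (a different joint-centre convention) before
    adding its own noise. Deterministic in ``(trial, tag, seed)``.
    """
    if tag not in ESTIMATOR_TAGS:
        raise ValueError(f"unknown estimator tag {tag!r}")
    if not trial.presence.all():
        raise ValueError("apply_estimator expects a fully present trial")
    rng = np.random.default_rng([seed, ESTIMATOR_TAGS.index(tag)])
    coords = trial.coords.copy()
    if tag == "B":
        hip_mid = coords[:, HIP_INDICES, :].mean(axis=1)
        drops = np.linalg.norm(coords[:, 6, :] - hip_mid, axis=1)
        leg_apparent = float(np.median(drops))
        # shift toward the hip: smaller y-drop in image coordinates
        coords[:, [4, 5, 6, 7], 1] -= offset_frac * leg_apparent
    coords += rng.normal(0.0, sigma_px, size=coords.shape)
    return replace(trial, coords=coords, presence=trial.presence.copy(), estimator=tag)


def inject_missingness(
    trial: KeypointTrial,
    interior_rate: float,
    boundary_rate: float,
    seed: int,
    window: tuple[int, int] | None = None,
) -> KeypointTrial:
    """Clear presence-mask cells at random.

    ``boundary_rate`` applies to the first and last frame of the analysis
    window (default: the whole trial), ``interior_rate`` to every other frame
    in the window. Boundary gaps are what make a trial invalid downstream,
    since they cannot be interpolated.
    """
    for name, rate in (("interior_rate", interior_rate), ("boundary_rate", boundary_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    lo, hi = window if window is not None else (0, trial.n_frames - 1)
    if not (0 <= lo <= hi < trial.n_frames):
        raise ValueError("window outside trial bounds")
    rng = np.random.default_rng(seed)
    presence = trial.presence.copy()
    n_win = hi - lo + 1
    draws = rng.random((n_win, N_JOINTS))
    rates = np.full((n_win, 1), interior_rate)
    rates[0, 0] = boundary_rate
    rates[-1, 0] = boundary_rate
    presence[lo : hi + 1][draws < rates] = False
    return replace(trial, coords=trial.coords.copy(), presence=presence)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def generate_dataset(
    n_subjects: int = 10,
    n_trials: int = 97,
    seed: int = 0,
    movement: str = "running",
    camera_view: str = "TS",
    estimators: Sequence[str] = ESTIMATOR_TAGS,
    missingness: dict[str, tuple[float, float]] | None = None,
    lead_in: int = 15,
    lead_out: int = 10,
) -> list[dict]:
    """Generate the default study dataset: ``n_trials`` running trials spread
    round-robin over ``n_subjects`` subjects, each observed by every estimator
    variant with its default dropout pattern.

    Returns a list of records, one per physical trial, with keys ``subject``,
    ``clean`` (noise-free trial), ``by_estimator`` (tag -> corrupted trial),
    ``force`` and ``events``.
    """
    if missingness is None:
        missingness = DEFAULT_MISSINGNESS
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(n_subjects, seed=int(rng.integers(2**31 - 1)))
    records: list[dict] = []
    for k in range(n_trials):
        subject = cohort[k % n_subjects]
        spec = default_trial_spec(rng, movement)
        spec = replace(spec, camera_view=camera_view)
        trial_seed = int(rng.integers(2**31 - 1))
        kp, force, events = generate_trial(subject, spec, trial_seed)
        kp = replace(
            kp,
            coords=kp.coords,
            presence=kp.presence,
            trial_id=f"{subject.subject_id}-r{k:03d}",
        )
        w_lo = max(0, events.heel_strike_frame - lead_in)
        w_hi = min(kp.n_frames - 1, events.toe_off_frame + lead_out)
        by_est: dict[str, KeypointTrial] = {}
        for tag in estimators:
            est = apply_estimator(kp, tag, seed=trial_seed)
            interior, boundary = missingness.get(tag, (0.0, 0.0))
            est = inject_missingness(
                est,
                interior,
                boundary,
                seed=int(rng.integers(2**31 - 1)),
                window=(w_lo, w_hi),
            )
            by_est[tag] = est
        records.append(
            {
                "subject": subject,
                "clean": kp,
                "by_estimator": by_est,
                "force": force,
                "events": events,
            }
        )
    return records


# ---------------------------------------------------------------------------
# writers emitting the pose-estimator dialects and the plate files
# ---------------------------------------------------------------------------

# inverse maps: analysis-joint index -> slot in each skeleton
_COCO17_SLOTS = (5, 6, 11, 12, 13, 14, 15, 16)
_BLAZE33_SLOTS = (11, 12, 23, 24, 25, 26, 27, 28)


def write_openpose_dir(trial: KeypointTrial, out_dir: str | Path, confidence: float = 0.9) -> Path:
    """Emit one OpenPose-style JSON file per frame (COCO-17 triplet list)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(trial.n_frames):
        triplets = [0.0] * (17 * 3)
        any_present = False
        for j, slot in enumerate(_COCO17_SLOTS):
            if trial.presence[i, j]:
                x, y = trial.coords[i, j]
                triplets[3 * slot : 3 * slot + 3] = [float(x), float(y), confidence]
                any_present = True
        payload = {
            "version": 1.3,
            "people": [{"pose_keypoints_2d": triplets}] if any_present else [],
        }
        (out / f"{trial.trial_id}_{i:012d}_keypoints.json").write_text(json.dumps(payload))
    return out


def write_alphapose_json(trial: KeypointTrial, path: str | Path, confidence: float = 0.9) -> Path:
    """Emit a single AlphaPose-style results JSON for the whole trial."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(trial.n_frames):
        if not trial.presence[i].any():
            continue  # no detection in this frame
        triplets = [0.0] * (17 * 3)
        for j, slot in enumerate(_COCO17_SLOTS):
            if trial.presence[i, j]:
                x, y = trial.coords[i, j]
                triplets[3 * slot : 3 * slot + 3] = [float(x), float(y), confidence]
        entries.append({"image_id": f"{i}.jpg", "keypoints": triplets, "score": 2.5})
    path.write_text(json.dumps(entries))
    return path


def write_blazepose_json(
    trial: KeypointTrial,
    path: str | Path,
    image_width: int = IMAGE_WIDTH,
    image_height: int = IMAGE_HEIGHT,
) -> Path:
    """Emit BlazePose-style per-frame landmark records with normalised
    coordinates — including the characteristic one-frame offset (record ``k``
    describes video frame ``k-1``; record 0 is a spurious duplicate), which
    the reader corrects by dropping the first record."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def frame_landmarks(i: int) -> list[dict]:
        lms = [{"x": 0.0, "y": 0.0, "visibility": 0.0} for _ in range(33)]
        for j, slot in enumerate(_BLAZE33_SLOTS):
            if trial.presence[i, j]:
                x, y = trial.coords[i, j]
                lms[slot] = {
                    "x": float(x) / image_width,
                    "y": float(y) / image_height,
                    "visibility": 0.95,
                }
        return lms

    records = [{"frame_index": 0, "landmarks": frame_landmarks(0)}]
    for i in range(trial.n_frames):
        records.append({"frame_index": i + 1, "landmarks": frame_landmarks(i)})
    path.write_text(json.dumps(records))
    return path


def write_force_csv(force: ForceTrial, path: str | Path) -> Path:
    """Force CSV with the documented header ``time_s,Fx_N,Fy_N,Fz_N``
    (Fx = medio-lateral, Fy = anterior-posterior, Fz = vertical)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(force.n_samples) / force.fs
    with path.open("w") as fh:
        fh.write("time_s,Fx_N,Fy_N,Fz_N\n")
        for i in range(force.n_samples):
            fh.write(
                f"{t[i]:.6f},{force.F[i, 0]:.6f},{force.F[i, 1]:.6f},{force.F[i, 2]:.6f}\n"
            )
    return path


def write_events_json(events: EventPair, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {
                "heel_strike_frame": events.heel_strike_frame,
                "toe_off_frame": events.toe_off_frame,
                "source": events.source,
            }
        )
    )
    return path
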