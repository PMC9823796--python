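"""Stance-window preprocessing chain for keypoint trials.

The pipeline order is fixed: extract window -> interpolate gaps -> smooth
(Savitzky-Golay) -> upsample to 200 Hz -> hip-centre -> stance crop ->
time-normalise to 101 frames. Gaps interior to the analysis window are closed
by linear interpolation; gaps touching the first or last window frame cannot
be interpolated and invalidate the trial (full-window or stance-only,
depending on where the gap reaches).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from pose2grf.types import (
    HIP_INDICES,
    N_INPUT_CHANNELS,
    N_JOINTS,
    EventPair,
    ForceTrial,
    KeypointTrial,
    NormalizedSample,
    WindowedTrial,
)


class InvalidTrialError(ValueError):
    """Raised when a trial cannot yield a valid stance-phase sample."""


def _interpolation_closure(presence: np.ndarray) -> np.ndarray:
    """Presence mask after linear interpolation: a cell becomes present iff it
    has a present neighbour somewhere before *and* after it in the window."""
    n = presence.shape[0]
    out = presence.copy()
    for j in range(presence.shape[1]):
        idx = np.flatnonzero(presence[:, j])
        if idx.size:
            out[idx[0] : idx[-1] + 1, j] = True
    return out


def extract_window(
    trial: KeypointTrial,
    events: EventPair,
    lead_in: int = 15,
    lead_out: int = 10,
) -> WindowedTrial:
    """Restrict a trial to stance plus lead-in/lead-out frames.

    The window always spans ``stance + lead_in + lead_out`` frames; frames
    falling outside the recorded trial are marked absent rather than
    fabricated, which clears the corresponding validity flag.
    """
    hs, to = events.heel_strike_frame, events.toe_off_frame
    if to <= hs:
        raise ValueError("toe off must come after heel strike")
    if hs >= trial.n_frames or to >= trial.n_frames:
        raise ValueError("events outside trial bounds")
    lo = hs - lead_in
    hi = to + lead_out  # inclusive
    n_win = hi - lo + 1
    coords = np.zeros((n_win, N_JOINTS, 2))
    presence = np.zeros((n_win, N_JOINTS), dtype=bool)
    src_lo = max(lo, 0)
    src_hi = min(hi, trial.n_frames - 1)
    coords[src_lo - lo : src_hi - lo + 1] = trial.coords[src_lo : src_hi + 1]
    presence[src_lo - lo : src_hi - lo + 1] = trial.presence[src_lo : src_hi + 1]
    win_trial = replace(trial, coords=coords, presence=presence)
    stance_start = lead_in
    stance_stop = lead_in + (to - hs)
    closure = _interpolation_closure(presence)
    return WindowedTrial(
        trial=win_trial,
        lead_in=lead_in,
        lead_out=lead_out,
        stance_start=stance_start,
        stance_stop=stance_stop,
        valid_full_window=bool(closure.all()),
        valid_stance=bool(closure[stance_start : stance_stop + 1].all()),
        interpolated=False,
    )


def interpolate_gaps(windowed: WindowedTrial) -> WindowedTrial:
    """Fill interior gaps per joint per axis by linear interpolation.

    Gaps touching the first or last window frame are left absent — they have
    no neighbour on one side — and the validity flags record that.
    """
    coords = windowed.coords.copy()
    presence = windowed.presence.copy()
    n = coords.shape[0]
    frames = np.arange(n)
    for j in range(N_JOINTS):
        idx = np.flatnonzero(presence[:, j])
        if idx.size < 2:
            continue
        span = slice(idx[0], idx[-1] + 1)
        for ax in range(2):
            coords[span, j, ax] = np.interp(frames[span], idx, coords[idx, j, ax])
        presence[span, j] = True
    ss, se = windowed.stance_start, windowed.stance_stop
    return replace(
        windowed,
        trial=replace(windowed.trial, coords=coords, presence=presence),
        valid_full_window=bool(presence.all()),
        valid_stance=bool(presence[ss : se + 1].all()),
        interpolated=True,
    )


def smooth(windowed: WindowedTrial, order: int = 3, window: int = 5) -> WindowedTrial:
    """Savitzky-Golay smoothing per joint per axis.

    Edges are handled by fitting the order-``order`` polynomial on the
    truncated one-sided window (scipy's ``mode='interp'``). Each joint's
    contiguous present span is smoothed; absent boundary frames are left
    untouched. Refuses series (or spans) shorter than the filter window.
    """
    if windowed.n_frames < window:
        raise ValueError(f"series of {windowed.n_frames} frames shorter than window {window}")
    coords = windowed.coords.copy()
    presence = windowed.presence
    for j in range(N_JOINTS):
        idx = np.flatnonzero(presence[:, j])
        if idx.size == 0:
            continue
        if np.any(np.diff(idx) != 1):
            raise ValueError(f"interior gaps remain for joint {j}; interpolate first")
        if idx.size < window:
            raise ValueError(f"present span of joint {j} shorter than window {window}")
        span = slice(idx[0], idx[-1] + 1)
        coords[span, j, :] = savgol_filter(
            coords[span, j, :], window_length=window, polyorder=order, axis=0, mode="interp"
        )
    return replace(windowed, trial=replace(windowed.trial, coords=coords, presence=presence.copy()))


def upsample(windowed: WindowedTrial, target_fs: float = 200.0) -> WindowedTrial:
    """Resample each joint trajectory onto a uniform ``target_fs`` grid
    spanning the same time interval (cubic spline; endpoints preserved).

    The stance sub-range is mapped onto the new grid by rounding its event
    times to the nearest sample.
    """
    fps = windowed.trial.fps
    if target_fs <= fps:
        raise ValueError("upsampling target must exceed the video frame rate")
    n = windowed.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames to upsample")
    t_old = np.arange(n) / fps
    n_out = int(round((n - 1) * target_fs / fps)) + 1
    t_new = np.linspace(0.0, t_old[-1], n_out)
    coords = np.zeros((n_out, N_JOINTS, 2))
    presence = np.zeros((n_out, N_JOINTS), dtype=bool)
    for j in range(N_JOINTS):
        idx = np.flatnonzero(windowed.presence[:, j])
        if idx.size == 0:
            continue
        if np.any(np.diff(idx) != 1):
            raise ValueError(f"interior gaps remain for joint {j}; interpolate first")
        keep = (t_new >= t_old[idx[0]] - 1e-12) & (t_new <= t_old[idx[-1]] + 1e-12)
        if idx.size >= 4:
            cs = CubicSpline(t_old[idx], windowed.coords[idx, j, :], axis=0)
            coords[keep, j, :] = cs(t_new[keep])
        else:
            for ax in range(2):
                coords[keep, j, ax] = np.interp(t_new[keep], t_old[idx], windowed.coords[idx, j, ax])
        presence[keep, j] = True
    ss = int(round(windowed.stance_start / fps * target_fs))
    se = int(round(windowed.stance_stop / fps * target_fs))
    trial = replace(windowed.trial, coords=coords, presence=presence, fps=target_fs)
    return replace(windowed, trial=trial, stance_start=ss, stance_stop=min(se, n_out - 1))


def hip_center(windowed: WindowedTrial) -> WindowedTrial:
    """Translate all joints into a moving frame whose origin is the mid-point
    of the two hips at every frame. Refuses if a hip is absent anywhere."""
    hips = windowed.presence[:, list(HIP_INDICES)]
    if not hips.all():
        raise ValueError("hip joints must be present at every frame to hip-centre")
    coords = windowed.coords.copy()
    mid = coords[:, list(HIP_INDICES), :].mean(axis=1, keepdims=True)
    coords = coords - mid
    coords[~windowed.presence] = 0.0
    return replace(windowed, trial=replace(windowed.trial, coords=coords, presence=windowed.presence.copy()))


def time_normalize(series: np.ndarray, n_out: int = 101, kind: str = "linear") -> np.ndarray:
    """Resample each column of a ``(T, k)`` matrix onto ``n_out`` points
    uniformly spanning ``[0, T-1]``; endpoints are preserved exactly."""
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    T = series.shape[0]
    if T < 2:
        raise ValueError("need at least 2 samples to time-normalise")
    x_old = np.arange(T, dtype=float)
    x_new = np.linspace(0.0, T - 1.0, n_out)
    if kind == "cubic" and T >= 4:
        out = CubicSpline(x_old, series, axis=0)(x_new)
    else:
        out = np.column_stack([np.interp(x_new, x_old, series[:, c]) for c in range(series.shape[1])])
    out[0] = series[0]
    out[-1] = series[-1]
    return out


def _crop_to_present_run(windowed: WindowedTrial) -> WindowedTrial:
    """Crop the window to the maximal contiguous all-joints-present run that
    contains the stance sub-range (needed when boundary gaps invalidate the
    full window but the stance itself is complete)."""
    all_present = windowed.presence.all(axis=1)
    ss, se = windowed.stance_start, windowed.stance_stop
    if not all_present[ss : se + 1].all():
        raise InvalidTrialError("stance phase incomplete after interpolation")
    lo = ss
    while lo > 0 and all_present[lo - 1]:
        lo -= 1
    hi = se
    while hi < windowed.n_frames - 1 and all_present[hi + 1]:
        hi += 1
    trial = replace(
        windowed.trial,
        coords=windowed.coords[lo : hi + 1].copy(),
        presence=windowed.presence[lo : hi + 1].copy(),
    )
    return replace(windowed, trial=trial, stance_start=ss - lo, stance_stop=se - lo)


def build_sample(
    windowed: WindowedTrial,
    force: ForceTrial,
    target_fs: float = 200.0,
    sg_order: int = 3,
    sg_window: int = 5,
) -> NormalizedSample:
    """Run the full chain on one interpolated window and pair it with its
    force record, yielding a 101x16 / 101x3 training sample.

    Requires a complete stance phase (``valid_stance``); trials whose lead-in
    or lead-out frames could not be interpolated are cropped to the maximal
    complete run around stance before smoothing.
    """
    from pose2grf import kinetics  # local import to avoid a cycle

    if not windowed.interpolated:
        windowed = interpolate_gaps(windowed)
    if not windowed.valid_stance:
        raise InvalidTrialError("trial has no complete stance phase")
    w = _crop_to_present_run(windowed)
    w = smooth(w, order=sg_order, window=sg_window)
    w = upsample(w, target_fs=target_fs)
    w = hip_center(w)
    stance = w.coords[w.stance_start : w.stance_stop + 1]  # (n_st, 8, 2)
    n_st = stance.shape[0]
    features = stance.reshape(n_st, N_INPUT_CHANNELS)  # joint-major, x before y
    inputs = time_normalize(features, n_out=101, kind="cubic")
    targets = kinetics.build_targets(force, keypoint_stance_samples=n_st, target_fs=target_fs)
    return NormalizedSample(
        subject_id=windowed.trial.subject_id,
        trial_id=windowed.trial.trial_id,
        estimator=windowed.trial.estimator,
        inputs=inputs,
        targets=targets,
    )


def assemble_inputs(samples: list[NormalizedSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into the ``[n, 101, 16]`` input and ``[n, 101, 3]``
    target tensors, ordered by (subject, trial, estimator)."""
    if not samples:
        raise ValueError("cannot assemble an empty sample list")
    ordered = sorted(samples, key=lambda s: s.key)
    for s in ordered:
        if s.inputs.shape != (101, N_INPUT_CHANNELS) or s.targets.shape != (101, 3):
            raise ValueError(f"shape mismatch in sample {s.key}")
    X = np.stack([s.inputs for s in ordered])
    Y = np.stack([s.targets for s in ordered])
    return X, Y
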