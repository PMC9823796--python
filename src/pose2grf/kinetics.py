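"""Force-plate processing and exercise-intensity statistics.

Stance is detected with a strict 20 N threshold on the vertical component.
Fmax is the maximum of the Euclidean norm of the three mass-normalised force
components; the instantaneous loading rate (ILR) is the ordinary
least-squares slope of the vertical force from stance onset to the impact
peak (the first local maximum of the vertical component), with a fallback
window of the first 13 % of stance on peakless curves. Both statistics are
computed on the 101-frame normalised curve, the quantity the network
predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pose2grf.types import ForceTrial

STANCE_THRESHOLD_N = 20.0


@dataclass(frozen=True)
class IntensityStats:
    """Per-trial intensity descriptors in mass-normalised units."""

    fmax: float  # N/kg
    ilr: float  # N/kg/s
    fmax_abs: float  # N
    mass: float  # kg


def read_force_csv(path: str | Path, fs: float = 2000.0, mass: float = 1.0) -> ForceTrial:
    """Read a force CSV with the required header ``time_s,Fx_N,Fy_N,Fz_N``
    (Fx = medio-lateral, Fy = anterior-posterior, Fz = vertical)."""
    df = pd.read_csv(path)
    required = ["time_s", "Fx_N", "Fy_N", "Fz_N"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"force CSV must have header {','.join(required)}, got {list(df.columns)}")
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        fs = 1.0 / np.median(np.diff(t))
    return ForceTrial(fs=float(fs), F=df[["Fx_N", "Fy_N", "Fz_N"]].to_numpy(), mass=mass)


def detect_stance(force: ForceTrial, threshold: float = STANCE_THRESHOLD_N) -> tuple[int, int] | None:
    """Find the stance interval on the vertical component.

    Onset is the first sample strictly above ``threshold``; offset is the last
    sample of the contiguous supra-threshold run starting there. Returns
    ``None`` when no sample exceeds the threshold.
    """
    above = force.vertical > threshold
    if not above.any():
        return None
    onset = int(np.argmax(above))
    run_end = onset
    while run_end + 1 < len(above) and above[run_end + 1]:
        run_end += 1
    return onset, run_end


def downsample_force(force: ForceTrial, target_fs: float = 200.0) -> ForceTrial:
    """Reduce the sampling rate: integer decimation when the ratio divides
    evenly (e.g. 2000 -> 200 Hz keeps every 10th sample), interpolation onto
    the uniform target grid otherwise."""
    if target_fs > force.fs:
        raise ValueError("downsampling target exceeds the source rate")
    ratio = force.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        step = int(round(ratio))
        F = force.F[::step].copy()
    else:
        t_old = np.arange(force.n_samples) / force.fs
        n_out = int(round(t_old[-1] * target_fs)) + 1
        t_new = np.linspace(0.0, t_old[-1], n_out)
        F = np.column_stack([np.interp(t_new, t_old, force.F[:, c]) for c in range(3)])
    return ForceTrial(fs=target_fs, F=F, mass=force.mass, meta=dict(force.meta))


def mass_normalize(force_values: np.ndarray, mass: float) -> np.ndarray:
    """Divide each force component by body mass; units become N/kg."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return np.asarray(force_values, dtype=float) / mass


def compute_fmax(grf: np.ndarray) -> float:
    """Maximum over time of the Euclidean norm of the 3-component GRF."""
    grf = np.asarray(grf, dtype=float)
    if grf.size == 0:
        raise ValueError("empty GRF matrix")
    if grf.ndim == 1:
        grf = grf[None, :]
    if not np.all(np.isfinite(grf)):
        raise ValueError("GRF matrix contains non-finite values")
    return float(np.linalg.norm(grf, axis=1).max())


def _first_local_max(v: np.ndarray, start: int, stop: int) -> int | None:
    """Index of the first interior local maximum of ``v`` in ``(start, stop)``."""
    for i in range(start + 1, stop):
        if v[i] > v[i - 1] and v[i] >= v[i + 1]:
            return i
    return None


def compute_ilr(
    vgrf: np.ndarray,
    fs: float,
    onset: int = 0,
    fallback_fraction: float = 0.13,
    search_fraction: float = 0.5,
) -> float:
    """Instantaneous loading rate: OLS slope of the vertical GRF versus time
    from stance onset to the impact peak.

    The impact peak is the first local maximum of the vertical component; if
    none occurs before ``search_fraction`` of stance, the window falls back to
    the first ``fallback_fraction`` of stance. Requires at least 5 samples.
    """
    v = np.asarray(vgrf, dtype=float)
    n = len(v) - onset
    if n < 5:
        raise ValueError("need at least 5 stance samples after onset for the ILR fit")
    peak = _first_local_max(v, onset, onset + int(search_fraction * n))
    if peak is None or peak - onset < 2:
        peak = onset + max(4, int(round(fallback_fraction * n)))
    peak = min(peak, len(v) - 1)
    t = np.arange(onset, peak + 1) / fs
    y = v[onset : peak + 1]
    if len(t) < 2 or np.ptp(t) == 0:
        raise ValueError("degenerate ILR window")
    slope = np.polyfit(t, y, 1)[0]
    return float(slope)


def intensity_stats(grf_101: np.ndarray, fs_equivalent: float, mass: float) -> IntensityStats:
    """Fmax and ILR of one 101x3 mass-normalised stance curve.

    ``fs_equivalent`` is the effective sampling rate of the normalised curve,
    i.e. ``100 / stance_duration`` — ILR is a per-second slope.
    """
    fmax = compute_fmax(grf_101)
    ilr = compute_ilr(grf_101[:, 2], fs=fs_equivalent, onset=0)
    return IntensityStats(fmax=fmax, ilr=ilr, fmax_abs=fmax * mass, mass=mass)


def build_targets(
    force: ForceTrial,
    keypoint_stance_samples: int,
    target_fs: float = 200.0,
    threshold: float = STANCE_THRESHOLD_N,
) -> np.ndarray:
    """Produce the 101x3 mass-normalised GRF target for one trial.

    Chain: detect stance on the raw record, crop, downsample to ``target_fs``,
    resample to the keypoint stance sample count (the keypoint stream is
    authoritative for the frame count), mass-normalise, time-normalise to 101.
    """
    from pose2grf.preprocess import time_normalize

    stance = detect_stance(force, threshold=threshold)
    if stance is None:
        raise ValueError("no stance phase found in force record")
    onset, offset = stance
    cropped = ForceTrial(
        fs=force.fs,
        F=force.F[onset : offset + 1],
        mass=force.mass,
        meta=dict(force.meta),
    )
    down = downsample_force(cropped, target_fs=target_fs)
    F = down.F
    if F.shape[0] != keypoint_stance_samples:
        F = time_normalize(F, n_out=keypoint_stance_samples, kind="linear")
    F = mass_normalize(F, force.mass)
    out = time_normalize(F, n_out=101, kind="linear")
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite target curve")
    return out
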