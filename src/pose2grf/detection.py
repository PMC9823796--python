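"""Keypoint detection-rate accounting.

Two completeness criteria per trial, both evaluated after interpolation:
(1) all 8 joints present at every frame of the full analysis window (stance
plus lead-in/lead-out) and (2) all joints present during the stance phase
only. Since interior gaps are always closed by interpolation, a trial fails
(1) exactly when a gap touches the first or last window frame, and fails (2)
when such a gap reaches into stance. Rates are tabulated by movement, camera
view and estimator, with pooled marginals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from pose2grf.preprocess import _interpolation_closure
from pose2grf.types import WindowedTrial


def trial_completeness(windowed: WindowedTrial) -> dict[str, bool]:
    """Evaluate both completeness criteria for one windowed trial.

    Works on interpolated and non-interpolated windows alike: the
    interpolation closure of the presence mask is what is scored.
    """
    closure = _interpolation_closure(windowed.presence)
    ss, se = windowed.stance_start, windowed.stance_stop
    return {
        "valid_full_window": bool(closure.all()),
        "valid_stance": bool(closure[ss : se + 1].all()),
    }


def detection_table(trials: list[WindowedTrial], margins: bool = True) -> pd.DataFrame:
    """Tabulate detection rates by (movement, camera_view, estimator).

    Returns one row per group with trial counts, valid counts and percentage
    rates, plus pooled marginal rows per estimator and overall (labelled
    ``all``). Empty groups simply do not appear; rates are never reported as
    0 for want of trials.
    """
    if not trials:
        raise ValueError("no trials to tabulate")
    rows = []
    for w in trials:
        flags = trial_completeness(w)
        rows.append(
            {
                "movement": w.trial.movement,
                "camera_view": w.trial.camera_view,
                "estimator": w.trial.estimator,
                "valid_full_window": flags["valid_full_window"],
                "valid_stance": flags["valid_stance"],
            }
        )
    df = pd.DataFrame(rows)

    def summarise(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        nf = int(g["valid_full_window"].sum())
        ns = int(g["valid_stance"].sum())
        return pd.Series(
            {
                "n_trials": n,
                "n_valid_full": nf,
                "n_valid_stance": ns,
                "rate_full": 100.0 * nf / n,
                "rate_stance": 100.0 * ns / n,
            }
        )

    grouped = (
        df.groupby(["movement", "camera_view", "estimator"])
        .apply(summarise, include_groups=False)
        .reset_index()
    )
    if margins:
        per_est = df.groupby("estimator").apply(summarise, include_groups=False).reset_index()
        per_est.insert(0, "movement", "all")
        per_est.insert(1, "camera_view", "all")
        overall = summarise(df).to_frame().T
        overall.insert(0, "movement", "all")
        overall.insert(1, "camera_view", "all")
        overall.insert(2, "estimator", "all")
        grouped = pd.concat([grouped, per_est, overall], ignore_index=True)
    for col in ("n_trials", "n_valid_full", "n_valid_stance"):
        grouped[col] = grouped[col].astype(int)
    return grouped


def write_detection_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path
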