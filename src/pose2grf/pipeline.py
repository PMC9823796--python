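"""Glue between the synthetic generator's trial records and the analysis.

A *record* (see :func:`pose2grf.synthetic.generate_dataset`) bundles one
physical trial: the subject, the clean keypoint trial, the per-estimator
corrupted trials, the force record and the events. These helpers run the
preprocessing chain over records to produce the windowed trials used by the
detection-rate analysis and the normalised samples used by the network.
"""

from __future__ import annotations

from typing import Sequence

from pose2grf import preprocess
from pose2grf.preprocess import InvalidTrialError
from pose2grf.types import NormalizedSample, WindowedTrial


def windows_from_records(
    records: Sequence[dict],
    lead_in: int = 15,
    lead_out: int = 10,
) -> list[WindowedTrial]:
    """Extract and interpolate the analysis window of every estimator trial."""
    out = []
    for rec in records:
        for trial in rec["by_estimator"].values():
            w = preprocess.extract_window(trial, rec["events"], lead_in=lead_in, lead_out=lead_out)
            out.append(preprocess.interpolate_gaps(w))
    return out


def samples_from_records(
    records: Sequence[dict],
    lead_in: int = 15,
    lead_out: int = 10,
    require_all_estimators: bool = True,
) -> list[NormalizedSample]:
    """Build normalised samples for every trial with a complete stance phase.

    The experiment design needs every physical trial observed by *all*
    estimator variants (paired comparisons); with
    ``require_all_estimators`` a trial is dropped entirely when any variant
    lacks a complete stance.
    """
    out: list[NormalizedSample] = []
    for rec in records:
        trial_samples = []
        ok = True
        for trial in rec["by_estimator"].values():
            w = preprocess.extract_window(trial, rec["events"], lead_in=lead_in, lead_out=lead_out)
            w = preprocess.interpolate_gaps(w)
            try:
                trial_samples.append(preprocess.build_sample(w, rec["force"]))
            except InvalidTrialError:
                ok = False
                if require_all_estimators:
                    break
        if ok or not require_all_estimators:
            out.extend(trial_samples)
    return out
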