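"""Leave-one-subject-out interchangeability experiments.

The experiment design enumerates, per held-out subject, one model fit per
training estimator (shared by test cases #1 and #2) plus one fit pooling all
estimators' keypoints (test case #3): with 3 estimators and 10 subjects that
is 40 fits. Within each fold one training subject is held out (seeded choice)
as the validation set used for best-epoch selection, so train, validation and
test sets are disjoint at subject level by construction.

Reporting follows the convention of the study design this emulates: grid
columns are the *training* estimator; row ``#1`` is same-estimator testing,
rows ``#2X`` are cross-estimator testing on estimator ``X``, and row ``#3``
is the pooled model tested on the column estimator. Delta conventions:
``delta_abs = truth - estimate`` and
``delta_percent = 100 * (estimate - truth) / truth`` (negative means
underestimation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from pose2grf import stats
from pose2grf.grf_net import GRFRegression, NetConfig
from pose2grf.kinetics import compute_fmax, compute_ilr
from pose2grf.preprocess import assemble_inputs
from pose2grf.types import ESTIMATOR_TAGS, NormalizedSample

#: Nominal stance duration (s) used to express ILR per second on the
#: 101-frame normalised-time grid; it cancels in all paired comparisons.
NOMINAL_STANCE_S = 0.22

COMPONENTS = ("ML", "AP", "vertical")


@dataclass(frozen=True)
class FitSpec:
    """One model fit of the plan: its training condition and test fold."""

    case: str  # "single" or "pooled"
    train_est: str  # estimator tag, or "ALL" for pooled fits
    fold_subject: str  # the held-out test subject


@dataclass(frozen=True)
class ExperimentPlan:
    """Enumeration of every model fit of the LOSO design."""

    subjects: tuple[str, ...]
    estimators: tuple[str, ...]
    fits: tuple[FitSpec, ...]

    @classmethod
    def make_plan(cls, subjects: Sequence[str], estimators: Sequence[str] = ESTIMATOR_TAGS) -> "ExperimentPlan":
        subjects = tuple(subjects)
        estimators = tuple(estimators)
        if len(subjects) < 2:
            raise ValueError("LOSO needs at least 2 subjects")
        if len(set(subjects)) != len(subjects):
            raise ValueError("duplicate subject ids in plan")
        if len(set(estimators)) != len(estimators) or not estimators:
            raise ValueError("estimators must be unique and non-empty")
        fits = [
            FitSpec(case="single", train_est=e, fold_subject=s)
            for e in estimators
            for s in subjects
        ]
        fits += [FitSpec(case="pooled", train_est="ALL", fold_subject=s) for s in subjects]
        return cls(subjects=subjects, estimators=estimators, fits=tuple(fits))

    @property
    def n_fits(self) -> int:
        return len(self.fits)


@dataclass
class PredictionRecord:
    """Predictions of one fitted model on one test set."""

    case: str  # "#1", "#2" or "#3"
    train_est: str
    test_est: str
    fold_subject: str
    trial_ids: list[str]
    pred: np.ndarray  # (m, 101, 3) N/kg
    truth: np.ndarray  # (m, 101, 3) N/kg
    best_epoch: int = 0


def _index_samples(samples: Sequence[NormalizedSample]):
    by = {}
    for s in samples:
        by.setdefault((s.subject_id, s.estimator), []).append(s)
    for v in by.values():
        v.sort(key=lambda s: s.trial_id)
    return by


def run_plan(
    plan: ExperimentPlan,
    samples: Sequence[NormalizedSample],
    config: NetConfig = NetConfig(),
    seed: int = 0,
    folds: Sequence[str] | None = None,
    verbose: bool = False,
) -> list[PredictionRecord]:
    """Execute (a subset of the folds of) an experiment plan.

    ``folds`` restricts training to the listed held-out subjects (a reduced
    plan for desk-scale runs); every fit of the restricted plan is still
    executed. Coverage of every (subject, estimator) cell is checked before
    any training starts. Deterministic in (plan, samples, config, seed).
    """
    by = _index_samples(samples)
    missing = [
        (s, e) for s in plan.subjects for e in plan.estimators if (s, e) not in by
    ]
    if missing:
        raise ValueError(f"missing sample coverage for {missing[:5]}{'...' if len(missing) > 5 else ''}")
    fold_subjects = list(folds) if folds is not None else list(plan.subjects)
    unknown = set(fold_subjects) - set(plan.subjects)
    if unknown:
        raise ValueError(f"folds {sorted(unknown)} not in plan")

    records: list[PredictionRecord] = []
    for fold_idx, test_subject in enumerate(fold_subjects):
        train_subjects = [s for s in plan.subjects if s != test_subject]
        rng = np.random.default_rng([seed, fold_idx])
        val_subject = train_subjects[int(rng.integers(len(train_subjects)))]
        core_subjects = [s for s in train_subjects if s != val_subject]
        if not core_subjects:
            raise ValueError(
                "running a fold needs at least 3 subjects (train, validation and test)"
            )

        def tensors(subjects: Sequence[str], ests: Sequence[str]):
            chunk = [smp for s in subjects for e in ests for smp in by[(s, e)]]
            X, Y = assemble_inputs(chunk)
            return X, Y, [c.subject_id for c in sorted(chunk, key=lambda s: s.key)]

        fits_here = [f for f in plan.fits if f.fold_subject == test_subject]
        for fit in fits_here:
            train_ests = list(plan.estimators) if fit.case == "pooled" else [fit.train_est]
            Xtr, Ytr, tr_ids = tensors(core_subjects, train_ests)
            Xv, Yv, _ = tensors([val_subject], train_ests)
            fit_seed = int(np.random.default_rng([seed, fold_idx, plan.fits.index(fit)]).integers(2**31 - 1))
            model = GRFRegression(
                Xtr, Ytr,
                config=NetConfig(**{**config.__dict__, "seed": fit_seed}),
                subject_ids=tr_ids,
            )
            res = model.fit(Xv, Yv, val_subject_ids=[val_subject])
            if verbose:
                print(f"fold {test_subject} train {fit.train_est}: best epoch {res.best_epoch}")
            for test_est in plan.estimators:
                test_samples = by[(test_subject, test_est)]
                Xte, Yte = assemble_inputs(test_samples)
                pred = res.predict(Xte)
                if fit.case == "pooled":
                    case = "#3"
                else:
                    case = "#1" if test_est == fit.train_est else "#2"
                records.append(
                    PredictionRecord(
                        case=case,
                        train_est=fit.train_est,
                        test_est=test_est,
                        fold_subject=test_subject,
                        trial_ids=[s.trial_id for s in sorted(test_samples, key=lambda s: s.key)],
                        pred=pred,
                        truth=Yte,
                        best_epoch=res.best_epoch,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _row_label(case: str, test_est: str) -> str:
    if case == "#2":
        return f"#2{test_est}"
    return case


@dataclass
class MetricsReport:
    """Evaluation grids plus intensity-parameter comparison tables.

    ``r_table`` / ``nrmse_table``: one row per (case, test estimator), one
    column per training estimator, mean over components then trials.
    ``component_r``: per-component means for case #1 cells.
    ``fmax_table`` / ``ilr_table``: long-format comparison of estimated vs
    ground-truth intensity parameters with paired t and Cohen's d.
    ``spm``: cluster summaries per cell and component.
    """

    r_table: pd.DataFrame
    nrmse_table: pd.DataFrame
    component_r: pd.DataFrame
    fmax_table: pd.DataFrame
    ilr_table: pd.DataFrame
    spm: dict = field(default_factory=dict)

    def summary(self) -> str:
        out = [
            "Interchangeability study - metrics report",
            "=" * 55,
            "Mean correlation r (components averaged, then trials):",
            self.r_table.round(3).to_string(),
            "",
            "nRMSE (range-normalised):",
            self.nrmse_table.round(3).to_string(),
            "",
            "Per-component r (same-estimator case #1):",
            self.component_r.round(3).to_string(),
            "",
            "Fmax comparison [N/kg] (delta_percent < 0 = underestimation):",
            self.fmax_table.round(3).to_string(index=False),
            "",
            "ILR comparison [N/kg/s]:",
            self.ilr_table.round(3).to_string(index=False),
        ]
        if self.spm:
            lines = ["", "SPM significant clusters (component: frame ranges):"]
            for cell, comps in sorted(self.spm.items()):
                frag = "; ".join(
                    f"{comp}: {clusters if clusters else 'none'}" for comp, clusters in comps.items()
                )
                lines.append(f"  {cell}: {frag}")
            out += lines
        return "\n".join(out)


def summarize(
    records: Sequence[PredictionRecord],
    estimators: Sequence[str] = ESTIMATOR_TAGS,
    alpha: float = 0.05,
    spm_permutations: int = 1000,
    spm_seed: int = 0,
    require_complete: bool = True,
) -> MetricsReport:
    """Aggregate a prediction store into the report grids.

    With ``require_complete`` every expected (row, column) cell must be
    present (at least for the folds that were run); missing cells are named.
    """
    if not records:
        raise ValueError("empty prediction store")
    cells: dict[tuple[str, str], list[PredictionRecord]] = {}
    for rec in records:
        cells.setdefault((_row_label(rec.case, rec.test_est), rec.train_est), []).append(rec)

    if require_complete:
        expected: list[tuple[str, str]] = []
        for e in estimators:
            expected.append(("#1", e))
            for x in estimators:
                if x != e:
                    expected.append((f"#2{x}", e))
            expected.append(("#3", "ALL"))
        missing = sorted(set(expected) - set(cells))
        if missing:
            raise ValueError(f"incomplete prediction store; missing cells {missing}")

    row_order = ["#1"] + [f"#2{x}" for x in estimators] + ["#3"]
    col_order = list(estimators) + ["ALL"]
    r_grid = pd.DataFrame(np.nan, index=row_order, columns=col_order)
    e_grid = pd.DataFrame(np.nan, index=row_order, columns=col_order)
    fmax_rows = []
    ilr_rows = []
    comp_r_rows = {}
    spm_out: dict[str, dict[str, list]] = {}
    fs_eq = 100.0 / NOMINAL_STANCE_S

    for (row, col), recs in sorted(cells.items()):
        pred = np.concatenate([r.pred for r in recs])
        truth = np.concatenate([r.truth for r in recs])
        r_per_trial = []
        e_per_trial = []
        comp_r = {c: [] for c in COMPONENTS}
        for m in range(pred.shape[0]):
            rs, es = [], []
            for ci, comp in enumerate(COMPONENTS):
                r = stats.pearson_r(pred[m, :, ci], truth[m, :, ci])
                e = stats.nrmse(pred[m, :, ci], truth[m, :, ci])
                if np.isfinite(r):
                    rs.append(r)
                    comp_r[comp].append(r)
                if np.isfinite(e):
                    es.append(e)
            r_per_trial.append(np.mean(rs))
            e_per_trial.append(np.mean(es))
        r_grid.loc[row, col] = float(np.mean(r_per_trial))
        e_grid.loc[row, col] = float(np.mean(e_per_trial))
        comp_r_rows[(row, col)] = {c: float(np.mean(v)) if v else np.nan for c, v in comp_r.items()}

        fmax_est = np.array([compute_fmax(pred[m]) for m in range(pred.shape[0])])
        fmax_tru = np.array([compute_fmax(truth[m]) for m in range(truth.shape[0])])
        ilr_est = np.array([compute_ilr(pred[m, :, 2], fs=fs_eq) for m in range(pred.shape[0])])
        ilr_tru = np.array([compute_ilr(truth[m, :, 2], fs=fs_eq) for m in range(truth.shape[0])])
        for name, est, tru, sink in (
            ("fmax", fmax_est, fmax_tru, fmax_rows),
            ("ilr", ilr_est, ilr_tru, ilr_rows),
        ):
            tt = stats.paired_ttest(est, tru, alpha=alpha)
            d, band = stats.cohens_d(est, tru)
            sink.append(
                {
                    "row": row,
                    "train_est": col,
                    "n": len(est),
                    "estimate": float(est.mean()),
                    "truth": float(tru.mean()),
                    "delta_abs": float(tru.mean() - est.mean()),
                    "delta_percent": float(100.0 * (est.mean() - tru.mean()) / tru.mean()),
                    "t": tt.t,
                    "p": tt.p,
                    "significant": tt.significant,
                    "d": d,
                    "band": band,
                }
            )

        if pred.shape[0] >= 3:
            comps = {}
            for ci, comp in enumerate(COMPONENTS):
                res = stats.spm_paired_t(
                    pred[:, :, ci], truth[:, :, ci],
                    alpha=alpha, n_permutations=spm_permutations, seed=spm_seed,
                )
                comps[comp] = res.clusters
            spm_out[f"{row}|train={col}"] = comps

    component_r = pd.DataFrame(
        [
            {"row": row, "train_est": col, **vals}
            for (row, col), vals in sorted(comp_r_rows.items())
        ]
    )
    return MetricsReport(
        r_table=r_grid.dropna(how="all").dropna(axis=1, how="all"),
        nrmse_table=e_grid.dropna(how="all").dropna(axis=1, how="all"),
        component_r=component_r,
        fmax_table=pd.DataFrame(fmax_rows),
        ilr_table=pd.DataFrame(ilr_rows),
        spm=spm_out,
    )


# ---------------------------------------------------------------------------
# statsmodels-style front door
# ---------------------------------------------------------------------------


class InterchangeabilityStudy:
    """The full estimator-interchangeability experiment as a fittable model.

    Built from a list of :class:`NormalizedSample` covering every
    (subject, estimator) combination; ``fit()`` trains every model of the
    (possibly fold-restricted) LOSO plan and returns a :class:`StudyResults`.
    """

    def __init__(
        self,
        samples: Sequence[NormalizedSample],
        estimators: Sequence[str] = ESTIMATOR_TAGS,
        config: NetConfig = NetConfig(),
    ):
        self.samples = list(samples)
        self.estimators = tuple(estimators)
        self.config = config
        subjects = sorted({s.subject_id for s in self.samples})
        self.plan = ExperimentPlan.make_plan(subjects, self.estimators)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "InterchangeabilityStudy":
        """Build from a long-format frame with columns ``subject_id``,
        ``trial_id``, ``estimator``, ``frame`` (0-100), the 16 input columns
        ``x0..y7`` and target columns ``ml, ap, vertical``."""
        samples = []
        input_cols = [f"{ax}{j}" for j in range(8) for ax in ("x", "y")]
        for key, g in df.groupby(["subject_id", "trial_id", "estimator"], sort=True):
            g = g.sort_values("frame")
            samples.append(
                NormalizedSample(
                    subject_id=str(key[0]),
                    trial_id=str(key[1]),
                    estimator=str(key[2]),
                    inputs=g[input_cols].to_numpy(),
                    targets=g[["ml", "ap", "vertical"]].to_numpy(),
                )
            )
        return cls(samples, **kwargs)

    def fit(
        self,
        seed: int = 0,
        folds: Sequence[str] | None = None,
        alpha: float = 0.05,
        spm_permutations: int = 1000,
        verbose: bool = False,
    ) -> "StudyResults":
        records = run_plan(
            self.plan, self.samples, config=self.config, seed=seed, folds=folds, verbose=verbose
        )
        metrics = summarize(
            records,
            estimators=self.estimators,
            alpha=alpha,
            spm_permutations=spm_permutations,
            spm_seed=seed,
        )
        return StudyResults(plan=self.plan, records=records, metrics=metrics, seed=seed)


@dataclass
class StudyResults:
    """Fitted interchangeability study: prediction store plus metric grids."""

    plan: ExperimentPlan
    records: list[PredictionRecord]
    metrics: MetricsReport
    seed: int

    def summary(self) -> str:
        head = [
            "Leave-one-subject-out interchangeability study",
            f"subjects: {len(self.plan.subjects)}, estimators: {', '.join(self.plan.estimators)}",
            f"plan: {self.plan.n_fits} fits; prediction sets: {len(self.records)}",
            "",
        ]
        return "\n".join(head) + self.metrics.summary()

    def save_store(self, path: str | Path) -> Path:
        """Persist the raw prediction store (arrays + provenance manifest)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        manifest = []
        arrays = {}
        for i, rec in enumerate(self.records):
            manifest.append(
                {
                    "case": rec.case,
                    "train_est": rec.train_est,
                    "test_est": rec.test_est,
                    "fold_subject": rec.fold_subject,
                    "trial_ids": rec.trial_ids,
                    "best_epoch": rec.best_epoch,
                }
            )
            arrays[f"pred_{i}"] = rec.pred
            arrays[f"truth_{i}"] = rec.truth
        np.savez(path, manifest=json.dumps({"seed": self.seed, "records": manifest}), **arrays)
        return path

    @staticmethod
    def load_store(path: str | Path) -> list[PredictionRecord]:
        with np.load(Path(path), allow_pickle=False) as data:
            manifest = json.loads(str(data["manifest"]))
            records = []
            for i, md in enumerate(manifest["records"]):
                records.append(
                    PredictionRecord(
                        case=md["case"],
                        train_est=md["train_est"],
                        test_est=md["test_est"],
                        fold_subject=md["fold_subject"],
                        trial_ids=md["trial_ids"],
                        pred=data[f"pred_{i}"],
                        truth=data[f"truth_{i}"],
                        best_epoch=md["best_epoch"],
                    )
                )
        return records
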