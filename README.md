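# pose2grf

Estimating three-component ground reaction forces (GRF) from 2D pose
keypoints, for sports-biomechanics practitioners who have sagittal video but
no force plate. The package implements the full workflow: parsers for three
pose-estimator output dialects (OpenPose/AlphaPose-style COCO-17 and
BlazePose-style 33-landmark streams), the stance-phase preprocessing chain,
keypoint detection-rate accounting, a bidirectional LSTM sequence regressor,
and a leave-one-subject-out (LOSO) interchangeability study across estimator
variants — exercised end to end on a built-in synthetic gait generator that
stands in for laboratory video/force recordings.

## The model

For each stance phase, hip-centred keypoint trajectories of eight joints
(bilateral shoulder, hip, knee, ankle), time-normalised to 101 frames, form
an input matrix `X ∈ R[101×16]`; the target is the mass-normalised GRF
`Y ∈ R[101×3]` (medio-lateral, anterior–posterior, vertical, N/kg). A
two-layer bidirectional LSTM (400 units per direction, dropout 0.5, Adam,
lr 0.003, 40 epochs, best-validation-epoch weights) learns `X → Y` under
LOSO cross-validation. Accuracy is scored per trial and component by
Pearson r and range-normalised RMSE; exercise-intensity parameters

* `Fmax = max_t ‖Y(t)‖₂` (peak resultant force, N/kg), and
* `ILR` — the OLS slope of the vertical GRF from stance onset to the impact
  peak (N/kg/s),

are compared by paired t-tests and Cohen's d, and whole curves by a
permutation-based statistical parametric mapping (SPM) test with max-|t|
family-wise control. Interchangeability asks whether a model trained on one
estimator's keypoints can score another's: the synthetic estimator variants
reproduce the canonical outcome that two same-convention estimators (A, O)
are interchangeable while a differently-trained one (B) causes systematic
force underestimation — a deficit of 2 N/kg per step accumulates to
`2 N/kg × 1000 steps × 63 kg = 126 kN` over a match.

## Worked example

```python
import numpy as np
from pose2grf import synthetic, pipeline
from pose2grf.experiments import InterchangeabilityStudy
from pose2grf.grf_net import NetConfig

records = synthetic.generate_dataset(n_subjects=10, n_trials=97, seed=1)
samples = pipeline.samples_from_records(records)      # 291 = 97 trials x 3 estimators
study = InterchangeabilityStudy(samples, config=NetConfig(hidden_units=48, epochs=40))
res = study.fit(seed=7)  # full 10-fold LOSO, ~11 min on one core
print(res.metrics.r_table.round(3))
```

which prints (columns = training estimator, rows = test case/test estimator):

```
         A      O      B    ALL
#1   0.648  0.593  0.628    NaN
#2A    NaN  0.608  0.616    NaN
#2O  0.587    NaN  0.567    NaN
#2B  0.589  0.581    NaN    NaN
#3     NaN    NaN    NaN  0.659
```

Mean r pools an unpredictable medio-lateral component (r ≈ 0) with highly
predictable anterior–posterior and vertical components (r ≈ 0.92–0.99); the
per-component table `res.metrics.component_r` makes that split explicit.
`res.metrics.fmax_table` carries the interchangeability verdict: same- and
cross-convention cells stay within a few percent of the true 24.6 N/kg Fmax
(train A / test O: −1.3 %, p = 0.07, trivial effect; pooled #3: +0.02 %),
while testing A- or O-trained models on B's keypoints underestimates Fmax
by 7–9 % with moderate-to-large effect sizes (train A / test B: −7.1 %,
p < 0.001, d = −1.08) — the systematic error whose cumulative consequence
the 126 kN example quantifies.

The same pipeline is scriptable from the shell:

```bash
pose2grf run --config cfg.yaml --out runs/demo   # simulate ... report, with manifest
```

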