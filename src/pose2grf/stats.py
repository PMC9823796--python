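"""Evaluation statistics for GRF curves and intensity parameters.

Curve agreement is scored per trial per component with Pearson's r and the
RMSE normalised by the ground-truth range. Scalar comparisons (Fmax, ILR)
use two-sided paired t-tests at alpha = 0.05 and paired Cohen's d, banded as
trivial (<0.20), small (0.20-0.60), moderate (0.60-1.20), large (1.20-2.0)
and very large (>2.0), boundaries assigned to the lower band.

Whole-curve differences use a statistical-parametric-mapping style test:
pointwise paired t statistics over the 101 frames with family-wise control
via a sign-flip permutation of the paired differences and a max-statistic
null distribution; significant clusters are maximal runs of frames whose
|t| exceeds the permutation threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


def pearson_r(pred: np.ndarray, truth: np.ndarray) -> float:
    """Sample Pearson correlation between two curves.

    Returns NaN (with a warning) when the truth is constant, so callers can
    exclude the pair.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    if np.ptp(truth) == 0:
        warnings.warn("constant ground-truth curve: correlation undefined, excluded")
        return np.nan
    if np.ptp(pred) == 0:
        return 0.0
    return float(np.corrcoef(pred, truth)[0, 1])


def nrmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """RMSE normalised by the ground-truth range (max - min) per curve."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    rng = np.ptp(truth)
    if rng == 0:
        warnings.warn("zero ground-truth range: nRMSE undefined, excluded")
        return np.nan
    return float(np.sqrt(np.mean((pred - truth) ** 2)) / rng)


_D_BANDS = ((0.20, "trivial"), (0.60, "small"), (1.20, "moderate"), (2.00, "large"))


def effect_band(d: float) -> str:
    """Magnitude label of a Cohen's d value; boundaries go to the lower band."""
    a = abs(d)
    for cut, name in _D_BANDS:
        if a <= cut:
            return name
    return "very large"


def cohens_d(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """Paired Cohen's d: mean(x - y) / sd(x - y), with its magnitude band.

    Returns (nan, 'undefined') when the differences have zero spread.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length samples of at least 2 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        return np.nan, "undefined"
    d = float(diff.mean() / sd)
    return d, effect_band(d)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    significant: bool
    n: int
    degenerate: bool = False
    note: str = ""


def paired_ttest(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> PairedTResult:
    """Two-sided paired-sample t-test; significant iff p < alpha.

    Zero-variance differences are degenerate: identical samples are reported
    as t = 0, non-significant; a constant non-zero difference is reported
    with a diagnostic instead of an unbounded statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    n = len(diff)
    if diff.std(ddof=1) == 0:
        if diff.mean() == 0:
            return PairedTResult(t=0.0, p=1.0, significant=False, n=n,
                                 degenerate=True, note="identical samples")
        return PairedTResult(t=np.nan, p=np.nan, significant=False, n=n,
                             degenerate=True,
                             note="constant non-zero difference; t undefined")
    t, p = sps.ttest_rel(x, y)
    return PairedTResult(t=float(t), p=float(p), significant=bool(p < alpha), n=n)


@dataclass
class SPMResult:
    """Outcome of the permutation-based curve comparison."""

    t_curve: np.ndarray
    threshold: float
    clusters: list[tuple[int, int]]  # inclusive frame ranges with |t| > threshold
    p_max: float  # permutation p-value of the observed max |t|
    alpha: float
    n_permutations: int

    @property
    def significant(self) -> bool:
        return bool(self.clusters)


def _pointwise_paired_t(diff: np.ndarray) -> np.ndarray:
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    safe = np.where(sd == 0, 1.0, sd)
    t = mean / (safe / np.sqrt(n))
    # zero spread: identical pairs -> t = 0; constant non-zero shift -> +/- inf
    with np.errstate(invalid="ignore"):
        return np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)


def spm_paired_t(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> SPMResult:
    """Paired comparison of two sets of 1D curves with family-wise control.

    ``curves_a`` and ``curves_b`` are ``(n, T)`` paired observations. The
    pointwise paired t statistic is computed per frame; the critical value is
    the ``1 - alpha`` quantile of the max-|t| distribution under random sign
    flips of the paired differences (the identity flip is always included, so
    the test is never anti-conservative). Clusters are maximal runs of frames
    exceeding the threshold.
    """
    A = np.asarray(curves_a, dtype=float)
    B = np.asarray(curves_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("paired curve sets must share an (n, T) shape")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pairs for the permutation test")
    D = A - B
    t_obs = _pointwise_paired_t(D)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    signs[0] = 1.0  # identity permutation
    # vectorised pointwise t under each sign flip: per-frame second moments
    sq_sum = (D**2).sum(axis=0)  # invariant under sign flips
    means = signs @ D / n  # (P, T)
    var = (sq_sum - n * means**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    safe = np.where(var == 0, 1.0, var)
    t_perm = means / np.sqrt(safe / n)
    with np.errstate(invalid="ignore"):
        t_perm = np.where(var == 0, np.where(means == 0, 0.0, np.sign(means) * np.inf), t_perm)
    max_abs = np.abs(t_perm).max(axis=1)
    k = int(np.ceil((1.0 - alpha) * (n_permutations + 1))) - 1
    threshold = float(np.sort(max_abs)[min(k, n_permutations - 1)])
    obs_max = float(np.abs(t_obs).max())
    p_max = float((np.sum(max_abs >= obs_max - 1e-12)) / n_permutations)

    above = np.abs(t_obs) > threshold
    clusters: list[tuple[int, int]] = []
    i = 0
    T = len(above)
    while i < T:
        if above[i]:
            j = i
            while j + 1 < T and above[j + 1]:
                j += 1
            clusters.append((i, j))
            i = j + 1
        else:
            i += 1
    return SPMResult(
        t_curve=t_obs,
        threshold=threshold,
        clusters=clusters,
        p_max=p_max,
        alpha=alpha,
        n_permutations=n_permutations,
    )


def cumulative_load(delta_per_step: float, n_steps: int, mass: float) -> float:
    """Cumulative force difference over repeated steps, in kN.

    ``delta_per_step`` [N/kg] x ``n_steps`` x ``mass`` [kg] / 1000.
    Example: 2 N/kg over 1000 steps for a 63 kg athlete -> 126 kN.
    """
    if delta_per_step < 0 or n_steps < 0 or mass < 0:
        raise ValueError("all inputs must be non-negative")
    return delta_per_step * n_steps * mass / 1000.0
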