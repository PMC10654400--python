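"""Validation statistics: AUC with DeLong comparison, RMSE with rank-sum
comparison, Williams' test for dependent correlations, calibration
(intercept, slope, observed/expected), patient-level bootstrap CIs, and a
simulation-based power analysis for the paired signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import N_DAYS


# ------------------------------------------------------------------- AUC

def auc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney probability, ties
    counted 1/2 (rank formulation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = sps.rankdata(scores)  # midranks handle ties
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placements(scores, labels):
    """DeLong placement values V10 (per positive) and V01 (per negative),
    via the midrank identity: the placement of a positive among negatives
    is its overall midrank minus its within-positives midrank."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[labels], scores[~labels]
    m, n = pos.size, neg.size
    all_ranks = sps.rankdata(scores)
    v10 = (all_ranks[labels] - sps.rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[~labels] - sps.rankdata(neg)) / m
    return v10, v01


def delong_test(scores_a, scores_b, labels):
    """DeLong's test for two correlated (paired) AUCs.

    Both score vectors are evaluated against the same labels; the
    covariance of the paired AUCs is estimated from placement values.
    Returns ``(z, p, (ci_lo, ci_hi), auc_a, auc_b)`` for the difference
    AUC_a - AUC_b (two-sided normal p; 95% CI).
    """
    labels = np.asarray(labels).astype(bool)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired DeLong needs aligned score and label vectors")
    m, n = int(labels.sum()), int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError("DeLong requires both classes present")
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, s in enumerate((scores_a, scores_b)):
        v10[i], v01[i] = _placements(s, labels)
        aucs[i] = v10[i].mean()
    s10 = np.cov(v10)  # 2x2, ddof=1
    s01 = np.cov(v01)
    cov = s10 / m + s01 / n
    diff = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        z = 0.0
    else:
        z = diff / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return float(z), float(p), (float(diff - half), float(diff + half)), float(aucs[0]), float(aucs[1])


def auc_variance_delong(scores, labels) -> float:
    """Single-AUC DeLong variance (used for jackknife cross-checks)."""
    labels = np.asarray(labels).astype(bool)
    v10, v01 = _placements(np.asarray(scores, dtype=float), labels)
    m, n = v10.size, v01.size
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


# ------------------------------------------------------------------ RMSE

def rmse(pred, truth) -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def rmse_compare(pred_a, pred_b, truth, paired: bool = False):
    """RMSE of two predictors plus a p-value for the difference.

    Default follows the published analysis exactly: the Wilcoxon *rank-sum*
    test applied to the two samples of per-patient squared errors. Because
    the errors are in fact paired (same patients), ``paired=True`` switches
    to the Wilcoxon signed-rank test on squared-error differences.
    """
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("aligned prediction and truth vectors required")
    se_a = (pred_a - truth) ** 2
    se_b = (pred_b - truth) ** 2
    if paired:
        d = se_a - se_b
        if np.allclose(d, 0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(se_a, se_b, zero_method="wilcox").pvalue)
    else:
        p = float(sps.ranksums(se_a, se_b).pvalue)
    return rmse(pred_a, truth), rmse(pred_b, truth), p


# -------------------------------------------------------------- Williams

def williams_test(r_ay: float, r_by: float, r_ab: float, n: int):
    """Williams' t for two dependent correlations sharing variable y.

    Tests r(A,y) = r(B,y) given the correlation r(A,B) between the two
    predictors, with n - 3 degrees of freedom (two-sided p).
    """
    if n <= 3:
        raise ValueError("Williams' test needs n > 3")
    for r in (r_ay, r_by, r_ab):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    detR = 1 - r_ay**2 - r_by**2 - r_ab**2 + 2 * r_ay * r_by * r_ab
    rbar = 0.5 * (r_ay + r_by)
    denom = 2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r_ab) ** 3
    t = (r_ay - r_by) * np.sqrt((n - 1) * (1 + r_ab) / denom)
    p = 2 * sps.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


# ----------------------------------------------------------- calibration

@dataclass
class CalibrationReport:
    objective: str
    oe_ratio: float
    intercept: float  # estimated with slope fixed at 1
    slope: float      # estimated freely (with free intercept)
    deciles: pd.DataFrame  # mean predicted vs mean observed per bin
    flags: list[str] = field(default_factory=list)


def _logit(p):
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return np.log(p / (1 - p))


def calibration(pred, outcome, objective: str, n_bins: int = 10) -> CalibrationReport:
    """Calibration summary for one day's predictions.

    Binary objectives: O/E = observed event rate / mean predicted
    probability; calibration intercept from a logistic model of the outcome
    on logit(p) with slope fixed at 1 (offset), and calibration slope from
    the free logistic recalibration. Continuous objective: least-squares of
    outcome on prediction (intercept with slope fixed at 1 = mean residual),
    and O/E = mean observed / mean predicted, an extension of the binary
    definition and labeled as such. A decile curve of mean observed vs mean
    predicted is attached in both modes.
    """
    pred = np.asarray(pred, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    flags: list[str] = []
    if np.ptp(pred) < 1e-12:
        flags.append("constant_predictions_slope_undefined")
        slope, intercept = np.nan, np.nan
        oe = float(outcome.mean() / pred.mean()) if pred.mean() != 0 else np.nan
    elif objective.startswith("binary"):
        x = _logit(pred)
        import statsmodels.api as sm

        free = sm.GLM(outcome, sm.add_constant(x), family=sm.families.Binomial()).fit()
        slope = float(free.params[1])
        fixed = sm.GLM(outcome, np.ones_like(x), offset=x,
                       family=sm.families.Binomial()).fit()
        intercept = float(fixed.params[0])
        oe = float(outcome.mean() / pred.mean())
    else:
        slope = float(np.polyfit(pred, outcome, 1)[0])
        intercept = float(np.mean(outcome - pred))  # slope fixed at 1
        oe = float(outcome.mean() / pred.mean()) if pred.mean() != 0 else np.nan
        flags.append("continuous_oe_is_extension")

    order = np.argsort(pred, kind="mergesort")
    bins = np.array_split(order, n_bins)
    bins = [b for b in bins if b.size]
    if len(bins) < 2:
        flags.append("fewer_than_two_populated_bins")
    deciles = pd.DataFrame(
        {
            "bin": np.arange(len(bins)),
            "n": [b.size for b in bins],
            "mean_predicted": [float(pred[b].mean()) for b in bins],
            "mean_observed": [float(outcome[b].mean()) for b in bins],
        }
    )
    return CalibrationReport(
        objective=objective, oe_ratio=oe, intercept=intercept, slope=slope,
        deciles=deciles, flags=flags,
    )


# -------------------------------------------------------------- bootstrap

def bootstrap_metric_ci(
    metric_fn,
    data: tuple,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
):
    """Percentile CI for ``metric_fn(*arrays)`` under patient-level
    resampling with replacement.

    Resamples on which the metric is undefined (raises) are redrawn; the
    redraw count is returned so degenerate data is visible, not hidden.
    """
    if B < 100:
        raise ValueError("bootstrap needs B >= 100")
    arrays = [np.asarray(a) for a in data]
    n = arrays[0].shape[0]
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    redraws = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        try:
            vals[b] = metric_fn(*(a[idx] for a in arrays))
        except (ValueError, ZeroDivisionError):
            redraws += 1
            if redraws > 100 * B:
                raise RuntimeError("bootstrap: metric undefined on almost all resamples")
            continue
        b += 1
    samples = np.sort(vals)
    alpha = (1 - level) / 2

    def at(q):
        pos = q * (B - 1)
        lo_i, hi_i = int(np.floor(pos)), int(np.ceil(pos))
        w = pos - lo_i
        return float((1 - w) * samples[lo_i] + w * samples[hi_i])

    return at(alpha), at(1 - alpha), redraws


# ------------------------------------------------------- power analysis

def _signed_rank_power(res_a, res_b, n: int, alpha: float, n_reps: int,
                       rng: np.random.Generator) -> float:
    """Monte-Carlo power of the paired signed-rank test at sample size n,
    drawing paired residual magnitudes from the two empirical distributions."""
    a = np.abs(np.asarray(res_a, dtype=float))
    b = np.abs(np.asarray(res_b, dtype=float))
    rejections = 0
    for _ in range(n_reps):
        xa = rng.choice(a, size=n, replace=True)
        xb = rng.choice(b, size=n, replace=True)
        d = xa - xb
        if np.allclose(d, 0):
            continue
        p = sps.wilcoxon(d, zero_method="wilcox", mode="approx").pvalue
        if p < alpha:
            rejections += 1
    return rejections / n_reps


def required_sample_size(
    residuals_model,
    residuals_reference,
    power: float = 0.90,
    alpha: float = 0.05,
    seed: int = 0,
    n_reps: int = 2000,
    n_max: int = 100000,
) -> int:
    """Smallest n at which the paired signed-rank test on residual
    magnitudes reaches the target power (Monte-Carlo, bracketing + binary
    search over n).

    Mirrors a prospective-study power calculation: the model's residual
    distribution versus a reference (e.g. predict-the-population-mean)
    residual distribution. Raises if the distributions are identical (no
    finite n achieves the power).
    """
    res_a = np.asarray(residuals_model, dtype=float)
    res_b = np.asarray(residuals_reference, dtype=float)
    if res_a.size == 0 or res_b.size == 0:
        raise ValueError("residual samples must be nonempty")
    if np.array_equal(np.sort(np.abs(res_a)), np.sort(np.abs(res_b))):
        raise ValueError("identical residual distributions: no finite sample size")
    rng = np.random.default_rng(seed)
    lo, hi = 5, 10
    while hi <= n_max:
        if _signed_rank_power(res_a, res_b, hi, alpha, n_reps, rng) >= power:
            break
        lo, hi = hi, hi * 2
    else:
        raise ValueError("power not reached below n_max; distributions too close")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _signed_rank_power(res_a, res_b, mid, alpha, n_reps, rng) >= power:
            hi = mid
        else:
            lo = mid
    return hi


# ------------------------------------------------------------ evaluation

@dataclass
class DayMetrics:
    day: int
    n: int
    n_excluded: int
    auc4: float | None = None
    auc4_ci: tuple | None = None
    auc6: float | None = None
    auc6_ci: tuple | None = None
    rmse: float | None = None
    rmse_ci: tuple | None = None
    pearson_r: float | None = None
    pearson_r_ci: tuple | None = None


@dataclass
class EvalReport:
    objective: str
    days: list[DayMetrics] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([d.__dict__ for d in self.days])


def evaluate_predictions(
    pred: np.ndarray,
    y: np.ndarray,
    avail: np.ndarray,
    objective: str = "continuous",
    bootstrap_B: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Per-day metrics on the patients available that day.

    Continuous predictions get RMSE, Pearson r, and AUCs for the
    binarized outcomes (pain > 4 and > 6); binary-objective probabilities
    get the matching single AUC. 95% bootstrap CIs resample patients.
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    avail = np.asarray(avail, dtype=bool)
    report = EvalReport(objective=objective)
    for d in range(N_DAYS):
        m = avail[:, d]
        pd_, yd = pred[m, d], y[m, d]
        dm = DayMetrics(day=d, n=int(m.sum()), n_excluded=int((~m).sum()))
        if m.sum() >= 2:
            if objective == "continuous":
                dm.rmse = rmse(pd_, yd)
                dm.rmse_ci = bootstrap_metric_ci(
                    rmse, (pd_, yd), B=bootstrap_B, seed=seed + d)[:2]
                if np.ptp(pd_) > 0 and np.ptp(yd) > 0:
                    dm.pearson_r = float(np.corrcoef(pd_, yd)[0, 1])
                    dm.pearson_r_ci = bootstrap_metric_ci(
                        lambda a, b: np.corrcoef(a, b)[0, 1],
                        (pd_, yd), B=bootstrap_B, seed=seed + 10 + d)[:2]
                for thr, attr in ((4, "auc4"), (6, "auc6")):
                    lab = yd > thr
                    if 0 < lab.sum() < lab.size:
                        setattr(dm, attr, auc(pd_, lab))
                        setattr(dm, attr + "_ci", bootstrap_metric_ci(
                            auc, (pd_, lab), B=bootstrap_B, seed=seed + 20 + d)[:2])
            else:
                thr = int(objective.split("@")[1])
                lab = yd > thr
                attr = "auc4" if thr == 4 else "auc6"
                if 0 < lab.sum() < lab.size:
                    setattr(dm, attr, auc(pd_, lab))
                    setattr(dm, attr + "_ci", bootstrap_metric_ci(
                        auc, (pd_, lab), B=bootstrap_B, seed=seed + 20 + d)[:2])
        report.days.append(dm)
    return report
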