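"""Validation statistics against independent oracles: pair-counting AUC,
jackknife DeLong variance, closed-form Williams' t, quantile bootstrap,
calibration direction, and signed-rank power analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from popset.stats import (
    auc,
    auc_variance_delong,
    bootstrap_metric_ci,
    calibration,
    delong_test,
    evaluate_predictions,
    required_sample_size,
    rmse,
    rmse_compare,
    williams_test,
)


# ------------------------------------------------------------------- AUC

def pair_counting_auc(scores, labels):
    """Oracle: exhaustive concordant-pair counting with ties at 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_worked_example():
    assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_auc_perfect_separation():
    assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc([1, 2, 3], [1, 1, 1])


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.integers(0, 2**31 - 1), st.integers(4, 50))
def test_auc_equals_pair_counting(seed, n):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
    labels = rng.random(n) < 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    assert auc(scores, labels) == pytest.approx(
        pair_counting_auc(scores, labels), abs=1e-12
    )


def test_auc_null_simulation():
    rng = np.random.default_rng(6)
    scores = rng.normal(size=10000)
    labels = rng.random(10000) < 0.4
    assert abs(auc(scores, labels) - 0.5) < 0.02


# ---------------------------------------------------------------- DeLong

def test_delong_identical_scores_null():
    rng = np.random.default_rng(1)
    s = rng.normal(size=80)
    labels = rng.random(80) < 0.5
    labels[:2] = [True, False]
    z, p, ci, a1, a2 = delong_test(s, s, labels)
    assert z == 0.0 and p == 1.0 and a1 == a2
    assert ci[0] <= 0.0 <= ci[1]


def test_delong_variance_matches_jackknife():
    rng = np.random.default_rng(2)
    n = 200
    labels = np.concatenate([np.ones(90, bool), np.zeros(110, bool)])
    scores = rng.normal(size=n) + labels
    var = auc_variance_delong(scores, labels)
    # oracle: leave-one-out jackknife recomputation of the AUC
    thetas = np.array([
        auc(np.delete(scores, i), np.delete(labels, i)) for i in range(n)
    ])
    var_jk = (n - 1) / n * ((thetas - thetas.mean()) ** 2).sum()
    assert abs(var - var_jk) / var_jk < 0.10


def test_delong_detects_a_real_difference():
    rng = np.random.default_rng(3)
    n = 600
    labels = rng.random(n) < 0.5
    labels[:2] = [True, False]
    good = labels + rng.normal(0, 0.8, n)
    bad = rng.normal(size=n)
    z, p, ci, a_good, a_bad = delong_test(good, bad, labels)
    assert a_good > a_bad and p < 1e-4 and ci[0] > 0


# ------------------------------------------------------------------ RMSE

def test_rmse_closed_cases():
    truth = np.array([1.0, 2.0, 3.0])
    a, b, p = rmse_compare(truth, truth + 2, truth)
    assert a == 0.0 and b == pytest.approx(2.0)


def test_rmse_compare_null_pvalues_uniform():
    rng = np.random.default_rng(4)
    pvals = []
    for _ in range(1000):
        truth = rng.normal(size=60)
        a = truth + rng.normal(0, 1, 60)
        b = truth + rng.normal(0, 1, 60)
        pvals.append(rmse_compare(a, b, truth)[2])
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_rmse_compare_paired_flag():
    rng = np.random.default_rng(5)
    truth = rng.normal(size=100)
    a = truth + rng.normal(0, 0.5, 100)
    b = truth + rng.normal(0, 2.0, 100)
    _, _, p = rmse_compare(a, b, truth, paired=True)
    assert p < 0.01
    _, _, p_same = rmse_compare(a, a, truth, paired=True)
    assert p_same == 1.0


def test_rmse_compare_length_mismatch():
    with pytest.raises(ValueError):
        rmse_compare([1, 2], [1, 2, 3], [1, 2, 3])


# -------------------------------------------------------------- Williams

def test_williams_equal_correlations_null():
    t, p = williams_test(0.4, 0.4, 0.3, 50)
    assert t == 0.0 and p == 1.0


def test_williams_matches_direct_formula():
    r_ay, r_by, r_ab, n = 0.5, 0.3, 0.2, 50
    t, p = williams_test(r_ay, r_by, r_ab, n)
    # oracle: independent arithmetic evaluation of the formula
    detR = 1 - r_ay**2 - r_by**2 - r_ab**2 + 2 * r_ay * r_by * r_ab
    rbar = (r_ay + r_by) / 2
    expect = (r_ay - r_by) * np.sqrt(
        (n - 1) * (1 + r_ab)
        / (2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r_ab) ** 3)
    )
    assert t == pytest.approx(expect, abs=1e-10)
    assert p == pytest.approx(2 * sps.t.sf(abs(expect), n - 3), abs=1e-10)


def test_williams_p_decreases_with_n():
    ps = [williams_test(0.5, 0.3, 0.2, n)[1] for n in (20, 50, 200, 1000)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_williams_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        williams_test(1.0, 0.3, 0.2, 50)
    with pytest.raises(ValueError):
        williams_test(0.5, 0.3, 0.2, 3)


# ----------------------------------------------------------- calibration

def test_perfect_continuous_calibration():
    rng = np.random.default_rng(7)
    pred = rng.uniform(0, 10, 500)
    rep = calibration(pred, pred, "continuous")
    assert rep.slope == pytest.approx(1.0, abs=1e-9)
    assert rep.intercept == pytest.approx(0.0, abs=1e-9)
    assert rep.oe_ratio == pytest.approx(1.0, abs=1e-12)


def test_overshrunk_predictions_give_slope_above_one():
    rng = np.random.default_rng(8)
    p_true = rng.uniform(0.05, 0.95, 20000)
    y = (rng.random(20000) < p_true).astype(float)
    shrunk = 0.5 + 0.5 * (p_true - 0.5)  # predictions pulled toward 0.5
    rep = calibration(shrunk, y, "binary@4")
    assert rep.slope > 1.0


def test_constant_predictions_flagged():
    rep = calibration(np.full(100, 0.3), np.zeros(100), "binary@4")
    assert "constant_predictions_slope_undefined" in rep.flags
    assert np.isnan(rep.slope)


def test_decile_curve_partitions_predictions():
    rng = np.random.default_rng(9)
    pred = rng.uniform(0, 1, 1000)
    y = (rng.random(1000) < pred).astype(float)
    rep = calibration(pred, y, "binary@4")
    assert rep.deciles["n"].sum() == 1000
    assert rep.deciles["mean_predicted"].is_monotonic_increasing


# -------------------------------------------------------------- bootstrap

def test_bootstrap_degenerate_data_zero_width():
    lo, hi, _ = bootstrap_metric_ci(lambda x: float(np.mean(x)),
                                    (np.full(50, 3.0),), B=200, seed=0)
    assert lo == hi == 3.0


def test_bootstrap_seeded_reproducibility():
    rng = np.random.default_rng(10)
    x = rng.normal(size=80)
    a = bootstrap_metric_ci(lambda v: float(np.mean(v)), (x,), B=300, seed=4)
    b = bootstrap_metric_ci(lambda v: float(np.mean(v)), (x,), B=300, seed=4)
    assert a == b


def test_bootstrap_redraws_on_undefined_metric():
    # single-class resamples make AUC fail; they must be redrawn and counted
    scores = np.array([0.1, 0.9, 0.8, 0.2])
    labels = np.array([0, 1, 1, 0])
    lo, hi, redraws = bootstrap_metric_ci(
        lambda s, l: auc(s, l), (scores, labels), B=100, seed=1)
    assert redraws > 0 and 0 <= lo <= hi <= 1


def test_bootstrap_requires_minimum_replicates():
    with pytest.raises(ValueError):
        bootstrap_metric_ci(lambda x: 0.0, (np.ones(5),), B=10)


# ------------------------------------------------------- power analysis

def test_required_sample_size_monotone_in_effect():
    rng = np.random.default_rng(11)
    base = np.abs(rng.normal(5, 1, 4000))
    small = np.abs(rng.normal(5.4, 1, 4000))
    large = np.abs(rng.normal(6.0, 1, 4000))
    n_small = required_sample_size(base, small, seed=1, n_reps=400)
    n_large = required_sample_size(base, large, seed=1, n_reps=400)
    assert n_large < n_small


def test_required_sample_size_identical_distributions_rejected():
    x = np.abs(np.random.default_rng(12).normal(5, 1, 100))
    with pytest.raises(ValueError):
        required_sample_size(x, x.copy(), seed=0, n_reps=100)


# ------------------------------------------------------------ evaluation

def test_evaluation_excludes_unavailable_patients_per_day(planted_setup):
    s = planted_setup
    from popset.train import encode_cohort
    data = encode_cohort(s["test"], s["dictionary"], s["schema"])
    pred = s["model"].predict(data["indices"], data["mask"], data["feats"])
    rep = evaluate_predictions(pred, data["y"], data["avail"],
                               bootstrap_B=100, seed=0)
    for d, dm in enumerate(rep.days):
        assert dm.n == int(data["avail"][:, d].sum())
        assert dm.n + dm.n_excluded == len(s["test"])
        if dm.rmse is not None:
            assert dm.rmse >= 0
            assert dm.rmse_ci[0] <= dm.rmse_ci[1]
        if dm.auc4 is not None:
            assert 0 <= dm.auc4 <= 1
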