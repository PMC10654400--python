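"""Leave-one-code-out deltas, bootstrap percentile CIs, and the
per-patient explanation report."""

import numpy as np
import pytest
from scipy import stats as sps

from popset.dictionary import index_codes
from popset.interpret import (
    code_effect,
    effect_ci,
    explain_patient,
    percentile_interval,
)
from popset.records import PatientRecord


def test_delta_equals_manual_two_call_difference(planted_setup):
    s = planted_setup
    rec = next(r for r in s["test"] if s["code"] in r.codes)
    delta = code_effect(s["model"], s["dictionary"], s["schema"], rec, s["code"])
    from popset.interpret import _predict_one, _without_code
    full = _predict_one(s["model"], s["dictionary"], s["schema"], rec)
    reduced = _predict_one(s["model"], s["dictionary"], s["schema"],
                           _without_code(rec, s["code"]))
    np.testing.assert_array_equal(delta, full - reduced)


def test_delta_requires_code_present(planted_setup):
    s = planted_setup
    rec = next(r for r in s["test"] if s["code"] not in r.codes)
    with pytest.raises(ValueError):
        code_effect(s["model"], s["dictionary"], s["schema"], rec, s["code"])


def test_single_code_record_delta_uses_empty_set_contract(planted_setup):
    s = planted_setup
    donor = s["test"][0]
    rec = PatientRecord(**{**donor.__dict__, "codes": {s["code"]: "ICD10"},
                           "patient_id": "single"})
    delta = code_effect(s["model"], s["dictionary"], s["schema"], rec, s["code"])
    from popset.interpret import _predict_one, _without_code
    empty_pred = _predict_one(s["model"], s["dictionary"], s["schema"],
                              _without_code(rec, s["code"]))
    full = _predict_one(s["model"], s["dictionary"], s["schema"], rec)
    np.testing.assert_array_equal(delta, full - empty_pred)


def test_planted_effect_recovered_by_delta(planted_setup):
    s = planted_setup
    carriers = [r for r in s["records"] if s["code"] in r.codes][:50]
    deltas = np.stack([
        code_effect(s["model"], s["dictionary"], s["schema"], r, s["code"])
        for r in carriers
    ])
    mean_delta = deltas.mean()
    assert 1.5 <= mean_delta <= 2.5  # planted +2 on every day


def test_sign_coherence_of_planted_positive_effect(planted_setup):
    s = planted_setup
    carriers = [r for r in s["records"] if s["code"] in r.codes][:200]
    deltas = np.stack([
        code_effect(s["model"], s["dictionary"], s["schema"], r, s["code"])
        for r in carriers
    ]).mean(axis=1)
    n_pos = int((deltas > 0).sum())
    p = sps.binomtest(n_pos, len(deltas), 0.5, alternative="greater").pvalue
    assert p < 0.01


def test_percentile_interval_matches_sort_based_oracle():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(9, 5))
    lo, hi = percentile_interval(x, level=0.95)
    # oracle: explicit sort and index arithmetic per column
    for col in range(5):
        srt = np.sort(x[:, col])
        for q, got in ((0.025, lo[col]), (0.975, hi[col])):
            pos = q * (len(srt) - 1)
            i = int(np.floor(pos))
            w = pos - i
            expect = (1 - w) * srt[i] + w * srt[min(i + 1, len(srt) - 1)]
            assert got == pytest.approx(expect, abs=1e-12)


def test_identical_members_give_zero_width_ci(small_ensemble, planted_setup):
    s = small_ensemble
    rec = next(r for r in s["records"] if "ICD-0001" in r.codes)
    clones = [s["members"][0]] * 3
    lo, hi, sig = effect_ci(clones, s["dictionary"], s["schema"], rec, "ICD-0001")
    np.testing.assert_allclose(lo, hi, atol=1e-12)


def test_significance_rule_is_ci_excludes_zero():
    # decision-rule fixture: (0.11, 0.71) significant, (-0.37, 0.25) not
    lo = np.array([0.11, -0.37, -0.9, 0.0, 0.1])
    hi = np.array([0.71, 0.25, -0.1, 0.4, 0.1])
    sig = (lo > 0) | (hi < 0)
    assert list(sig) == [True, False, True, False, True]


def test_effect_ci_needs_two_members(small_ensemble):
    s = small_ensemble
    rec = next(r for r in s["records"] if "ICD-0001" in r.codes)
    with pytest.raises(ValueError):
        effect_ci(s["members"][:1], s["dictionary"], s["schema"], rec, "ICD-0001")


def test_explain_patient_report_structure(small_ensemble):
    s = small_ensemble
    model = s["members"][0]["model"]
    rec = next(r for r in s["records"]
               if len([c for c in r.codes if c in s["dictionary"]]) >= 3)
    report = explain_patient(model, s["members"], s["dictionary"],
                             s["schema"], rec)
    n_in_dict = len([c for c in rec.codes if c in s["dictionary"]])
    assert len(report.rows) == n_in_dict
    weights = np.array([r.attention_weight for r in report.rows])
    assert weights.sum() == pytest.approx(1.0, abs=1e-6)
    assert (np.diff(weights) <= 1e-12).all()  # descending attention order
    assert np.all(report.pred_ci_low <= report.pred_ci_high)
    md = report.to_markdown()
    assert "Attention Weight" in md and report.rows[0].code in md


def test_explain_patient_deterministic(small_ensemble):
    s = small_ensemble
    model = s["members"][0]["model"]
    rec = next(r for r in s["records"] if r.codes)
    a = explain_patient(model, s["members"], s["dictionary"], s["schema"], rec)
    b = explain_patient(model, s["members"], s["dictionary"], s["schema"], rec)
    assert a.to_dict() == b.to_dict()


def test_top_attention_rank_recovers_planted_code(planted_setup):
    s = planted_setup
    carriers = [
        r for r in s["records"]
        if s["code"] in r.codes
        and len([c for c in r.codes if c in s["dictionary"]]) > 1
    ][:200]
    assert len(carriers) == 200
    top = 0
    for rec in carriers:
        idx, mask, _ = index_codes(rec, s["dictionary"])
        w = s["model"].attention_weights(idx[None, :], mask[None, :])[0]
        slots = np.where(mask)[0]
        best = slots[np.argmax(w[slots])]
        top += s["dictionary"].index_to_code[int(idx[best])] == s["code"]
    assert top / len(carriers) >= 0.70
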