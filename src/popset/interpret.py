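"""Per-patient explanations: attention-ranked codes and leave-one-code-out
effect estimates with bootstrap confidence intervals.

The effect of a code on a patient's predicted pain is estimated
counterfactually: predict for the patient as given, predict again for an
identical patient with that single code removed from their set, and report
the per-day difference (positive = the code increases predicted pain).
Point estimates come from the primary fitted model; uncertainty comes from
an ensemble of models fitted on bootstrap resamples of the training
patients, summarized by percentile intervals. Because the model is
associational, these deltas are predictive contrasts, not causal effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import CodeDictionary, index_codes
from .features import FeatureSchema
from .model import PopsModel
from .records import N_DAYS, PatientRecord


@dataclass
class CodeEffectRow:
    code: str
    kind: str
    attention_weight: float
    delta: np.ndarray  # (5,)
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # bool (5,): CI excludes 0


@dataclass
class CodeEffectReport:
    patient_id: str
    predictions: np.ndarray  # (5,) point predictions
    pred_ci_low: np.ndarray
    pred_ci_high: np.ndarray
    rows: list[CodeEffectRow] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "predictions": self.predictions.tolist(),
            "pred_ci_low": self.pred_ci_low.tolist(),
            "pred_ci_high": self.pred_ci_high.tolist(),
            "codes": [
                {
                    "code": r.code,
                    "kind": r.kind,
                    "attention_weight": r.attention_weight,
                    "delta": r.delta.tolist(),
                    "ci_low": r.ci_low.tolist(),
                    "ci_high": r.ci_high.tolist(),
                    "significant": r.significant.tolist(),
                }
                for r in self.rows
            ],
        }

    def to_markdown(self) -> str:
        """Render in the style of a per-patient effect table: one row per
        code, descending attention weight, bold where the CI excludes 0."""
        days = " | ".join(f"Day {d}" for d in range(N_DAYS))
        lines = [
            f"**Patient {self.patient_id}** — predicted max pain: "
            + ", ".join(
                f"{p:.2f} ({lo:.2f}, {hi:.2f})"
                for p, lo, hi in zip(
                    self.predictions, self.pred_ci_low, self.pred_ci_high
                )
            ),
            "",
            f"| Code | Attention Weight | {days} |",
            "|---" * (N_DAYS + 2) + "|",
        ]
        for r in self.rows:
            cells = []
            for d in range(N_DAYS):
                cell = f"{r.delta[d]:.2f} ({r.ci_low[d]:.2f}, {r.ci_high[d]:.2f})"
                cells.append(f"**{cell}**" if r.significant[d] else cell)
            lines.append(
                f"| {r.kind} {r.code} | {r.attention_weight:.4f} | "
                + " | ".join(cells)
                + " |"
            )
        return "\n".join(lines)


def _predict_one(model, dictionary, schema, record) -> np.ndarray:
    idx, mask, _ = index_codes(record, dictionary)
    feats = schema.transform(record)[None, :]
    return model.predict(idx[None, :], mask[None, :], feats)[0]


def _without_code(record: PatientRecord, code: str) -> PatientRecord:
    codes = {c: k for c, k in record.codes.items() if c != code}
    out = PatientRecord(**{**record.__dict__, "codes": codes})
    return out


def code_effect(
    model: PopsModel,
    dictionary: CodeDictionary,
    schema: FeatureSchema,
    record: PatientRecord,
    code: str,
) -> np.ndarray:
    """Leave-one-code-out delta: prediction with the code minus prediction
    for an identical patient with the code removed (5-vector)."""
    if code not in record.codes or code not in dictionary:
        raise ValueError(f"code {code!r} not in the record's indexed set")
    full = _predict_one(model, dictionary, schema, record)
    reduced = _predict_one(model, dictionary, schema, _without_code(record, code))
    return full - reduced


def percentile_interval(samples: np.ndarray, level: float = 0.95):
    """Percentile bounds by sorting and linear interpolation between order
    statistics (matches an explicit sort-and-index computation)."""
    samples = np.sort(np.asarray(samples, dtype=float), axis=0)
    alpha = (1.0 - level) / 2.0
    n = samples.shape[0]

    def at(q):
        pos = q * (n - 1)
        lo_i = int(np.floor(pos))
        hi_i = int(np.ceil(pos))
        w = pos - lo_i
        return (1 - w) * samples[lo_i] + w * samples[hi_i]

    return at(alpha), at(1.0 - alpha)


def effect_ci(
    ensemble: list[dict],
    dictionary: CodeDictionary,
    schema: FeatureSchema,
    record: PatientRecord,
    code: str,
    level: float = 0.95,
):
    """Percentile CI over the ensemble members' per-day deltas.

    ``significant[d]`` is True when the interval excludes zero (the bold
    rule in the effect tables).
    """
    if len(ensemble) < 2:
        raise ValueError("effect CIs need an ensemble of B >= 2 models")
    deltas = np.stack(
        [
            code_effect(m["model"], dictionary, schema, record, code)
            for m in ensemble
        ]
    )
    lo, hi = percentile_interval(deltas, level)
    significant = (lo > 0) | (hi < 0)
    return lo, hi, significant


def explain_patient(
    model: PopsModel,
    ensemble: list[dict],
    dictionary: CodeDictionary,
    schema: FeatureSchema,
    record: PatientRecord,
    level: float = 0.95,
) -> CodeEffectReport:
    """Full per-patient report: predictions with ensemble CIs and one row
    per in-dictionary code, sorted by descending attention weight."""
    idx, mask, _ = index_codes(record, dictionary)
    feats = schema.transform(record)[None, :]
    preds = model.predict(idx[None, :], mask[None, :], feats)[0]
    member_preds = np.stack(
        [m["model"].predict(idx[None, :], mask[None, :], feats)[0] for m in ensemble]
    ) if ensemble else preds[None, :]
    p_lo, p_hi = percentile_interval(member_preds, level)

    report = CodeEffectReport(
        patient_id=record.patient_id,
        predictions=preds,
        pred_ci_low=p_lo,
        pred_ci_high=p_hi,
    )
    present = mask.sum()
    if present == 0:
        return report
    weights = model.attention_weights(idx[None, :], mask[None, :])[0]
    index_to_code = dictionary.index_to_code
    rows = []
    for slot in range(int(present)):
        code = index_to_code[int(idx[slot])]
        delta = code_effect(model, dictionary, schema, record, code)
        if len(ensemble) >= 2:
            lo, hi, sig = effect_ci(ensemble, dictionary, schema, record, code, level)
        else:
            lo, hi = delta.copy(), delta.copy()
            sig = np.zeros(N_DAYS, dtype=bool)
        rows.append(
            CodeEffectRow(
                code=code,
                kind=record.codes[code],
                attention_weight=float(weights[slot]),
                delta=delta,
                ci_low=lo,
                ci_high=hi,
                significant=sig,
            )
        )
    rows.sort(key=lambda r: (-r.attention_weight, r.code))
    report.rows = rows
    return report
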