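"""Structured-feature schema: z-scored continuous variables and one-hot
categoricals, with statistics fitted on the training split only."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

CONTINUOUS_FIELDS = ("age", "weight", "height", "preop_pain")
CATEGORICAL_FIELDS = ("sex", "race", "service", "urgency")
OTHER_SLOT = "__other__"


@dataclass
class FeatureSchema:
    """Normalization and encoding statistics for the structured inputs.

    Continuous fields are imputed with the training median and z-scored
    with training mean/SD. Categorical fields are one-hot encoded against
    the training vocabulary with a trailing "other/unknown" slot; the
    inpatient flag is a single 0/1 column. Column order is fixed:
    continuous fields in declaration order, then each categorical field's
    sorted vocabulary + other slot, then inpatient.
    """

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    medians: dict[str, float] = field(default_factory=dict)
    vocabularies: dict[str, list[str]] = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return (
            len(CONTINUOUS_FIELDS)
            + sum(len(v) + 1 for v in self.vocabularies.values())
            + 1
        )

    def column_names(self) -> list[str]:
        names = list(CONTINUOUS_FIELDS)
        for f in CATEGORICAL_FIELDS:
            names.extend(f"{f}={c}" for c in self.vocabularies[f])
            names.append(f"{f}={OTHER_SLOT}")
        names.append("inpatient")
        return names

    @classmethod
    def fit(cls, records) -> "FeatureSchema":
        if not records:
            raise ValueError("cannot fit a schema on zero records")
        schema = cls()
        for f in CONTINUOUS_FIELDS:
            vals = np.array(
                [getattr(r, f) for r in records if getattr(r, f) is not None],
                dtype=float,
            )
            if vals.size == 0:
                vals = np.array([0.0])
            schema.medians[f] = float(np.median(vals))
            schema.means[f] = float(np.mean(vals))
            sd = float(np.std(vals, ddof=0))
            schema.sds[f] = sd if sd > 0 else 1.0
        for f in CATEGORICAL_FIELDS:
            schema.vocabularies[f] = sorted({str(getattr(r, f)) for r in records})
        return schema

    def transform(self, record) -> np.ndarray:
        x = np.zeros(self.dim)
        j = 0
        for f in CONTINUOUS_FIELDS:
            v = getattr(record, f)
            if v is None or not np.isfinite(v):
                v = self.medians[f]
            x[j] = (float(v) - self.means[f]) / self.sds[f]
            j += 1
        for f in CATEGORICAL_FIELDS:
            vocab = self.vocabularies[f]
            val = str(getattr(record, f))
            if val in vocab:
                x[j + vocab.index(val)] = 1.0
            else:
                x[j + len(vocab)] = 1.0  # other/unknown slot
            j += len(vocab) + 1
        x[j] = 1.0 if record.inpatient else 0.0
        return x

    def transform_many(self, records) -> np.ndarray:
        return np.stack([self.transform(r) for r in records])

    def to_json(self) -> str:
        return json.dumps(
            {
                "means": self.means,
                "sds": self.sds,
                "medians": self.medians,
                "vocabularies": self.vocabularies,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        return cls(
            means=d["means"],
            sds=d["sds"],
            medians=d["medians"],
            vocabularies=d["vocabularies"],
        )


def make_features(record, schema: FeatureSchema) -> np.ndarray:
    """Numeric feature vector for one record under a fitted schema."""
    return schema.transform(record)
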