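"""Code dictionary: frequency-thresholded vocabulary of CPT/ICD-10 codes.

A code enters the dictionary iff it appears in at least ``min_frequency`` of
records (default 1 in 10,000). Index 0 is reserved for padding; real codes
get dense indices 1..V ordered by descending record frequency (ties broken
lexicographically) so that indexing is deterministic.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

DICT_FORMAT_VERSION = 1
PAD_INDEX = 0
DEFAULT_MIN_FREQUENCY = 1e-4
DEFAULT_MAX_SET_SIZE = 130


@dataclass
class CodeDictionary:
    code_to_index: dict[str, int]
    frequencies: dict[str, float]  # record frequency (membership, not counts)
    min_frequency: float = DEFAULT_MIN_FREQUENCY
    max_set_size: int = DEFAULT_MAX_SET_SIZE

    def __len__(self) -> int:
        return len(self.code_to_index)

    def __contains__(self, code: str) -> bool:
        return code in self.code_to_index

    @property
    def index_to_code(self) -> dict[int, str]:
        return {i: c for c, i in self.code_to_index.items()}

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": DICT_FORMAT_VERSION,
                "min_frequency": self.min_frequency,
                "max_set_size": self.max_set_size,
                "codes": [
                    {"code": c, "index": i, "frequency": self.frequencies[c]}
                    for c, i in sorted(self.code_to_index.items(), key=lambda kv: kv[1])
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CodeDictionary":
        d = json.loads(text)
        if d.get("format_version") != DICT_FORMAT_VERSION:
            raise ValueError("unsupported dictionary format version")
        return cls(
            code_to_index={e["code"]: e["index"] for e in d["codes"]},
            frequencies={e["code"]: e["frequency"] for e in d["codes"]},
            min_frequency=d["min_frequency"],
            max_set_size=d["max_set_size"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "CodeDictionary":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_dictionary(
    records,
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
) -> CodeDictionary:
    """Build the vocabulary from record membership counts.

    Each record contributes each code at most once (``PatientRecord.codes``
    is a mapping, so duplicates cannot occur within a record by
    construction). Inclusion rule: records-containing / total-records >=
    ``min_frequency``.
    """
    if not records:
        raise ValueError("cannot build a dictionary from zero records")
    n = len(records)
    counts: Counter[str] = Counter()
    for rec in records:
        counts.update(set(rec.codes))
    freqs = {c: k / n for c, k in counts.items() if k / n >= min_frequency}
    # descending frequency, lexicographic tie-break; indices start at 1
    ordered = sorted(freqs, key=lambda c: (-freqs[c], c))
    code_to_index = {c: i + 1 for i, c in enumerate(ordered)}
    return CodeDictionary(
        code_to_index=code_to_index,
        frequencies=freqs,
        min_frequency=min_frequency,
        max_set_size=max_set_size,
    )


def index_codes(
    record, dictionary: CodeDictionary
) -> tuple[np.ndarray, np.ndarray, int]:
    """Map a record's code set to padded dictionary indices.

    Returns ``(indices, present_mask, n_dropped)`` where ``indices`` has
    length ``max_set_size`` (0 = pad) and ``n_dropped`` counts
    out-of-dictionary codes. If the set exceeds ``max_set_size``, the
    lowest-frequency (most specific) codes are kept.
    """
    in_dict = [c for c in record.codes if c in dictionary]
    n_dropped = len(record.codes) - len(in_dict)
    # ascending frequency, then lexicographic: deterministic, rarest first
    in_dict.sort(key=lambda c: (dictionary.frequencies[c], c))
    kept = in_dict[: dictionary.max_set_size]
    S = dictionary.max_set_size
    indices = np.zeros(S, dtype=np.int64)
    mask = np.zeros(S, dtype=bool)
    for i, c in enumerate(kept):
        indices[i] = dictionary.code_to_index[c]
        mask[i] = True
    return indices, mask, n_dropped
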