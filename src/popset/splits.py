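"""Cohort partitioning and training-set augmentation."""

from __future__ import annotations

import copy

import numpy as np

AUG_SUFFIX = "#noCPT"


def split_cohort(records, fractions=(0.81, 0.09, 0.10), seed: int = 0):
    """Uniform random disjoint partition into train/validation/test.

    Sizes are floor allocations of ``fractions``; any remainder goes to the
    largest fraction (first one on ties). Seeded and reproducible.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(records)
    sizes = [int(np.floor(f * n)) for f in fractions]
    sizes[int(np.argmax(fractions))] += n - sum(sizes)
    perm = np.random.default_rng(seed).permutation(n)
    out = []
    start = 0
    for s in sizes:
        out.append([records[i] for i in perm[start : start + s]])
        start += s
    return tuple(out)


def augment_training(train_records):
    """Duplicate each patient that carries CPT codes, with CPT codes removed.

    The copy keeps ICD codes, features and pain observations unchanged, and
    gets a derived patient id (``<id>#noCPT``). Patients with no CPT codes
    are not duplicated (the copy would be identical). Only the training
    split is ever augmented.
    """
    out = list(train_records)
    for rec in train_records:
        if any(k == "CPT" for k in rec.codes.values()):
            dup = copy.deepcopy(rec)
            dup.patient_id = rec.patient_id + AUG_SUFFIX
            dup.codes = {c: k for c, k in rec.codes.items() if k != "CPT"}
            out.append(dup)
    return out


def base_patient_id(patient_id: str) -> str:
    """Original id of a possibly augmented record."""
    return patient_id.split(AUG_SUFFIX)[0]
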