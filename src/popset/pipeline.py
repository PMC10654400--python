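"""End-to-end pipeline: simulate/ingest -> exclusions -> dictionary ->
split -> augment -> fit (+ ensemble) -> evaluate -> explain, with every
intermediate persisted and config hashes recorded in each artifact."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .dictionary import build_dictionary, CodeDictionary
from .features import FeatureSchema
from .interpret import explain_patient
from .io import read_cohort, write_cohort
from .model import ModelConfig, PopsModel
from .records import apply_exclusions
from .simulate import SimConfig, generate_cohort, config_to_dict
from .splits import augment_training, split_cohort
from .stats import evaluate_predictions
from .train import TrainConfig, encode_cohort, ensemble_fit, fit


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    cohort_path: str | None = None  # None -> simulate
    sim: SimConfig = field(default_factory=SimConfig)
    objective: str = "continuous"
    min_frequency: float = 1e-4
    max_set_size: int = 130
    split_fractions: tuple = (0.81, 0.09, 0.10)
    embed_dim: int = 32
    n_heads: int = 4
    ffn_hidden: tuple = (64, 32)
    dropout: float = 0.1
    batch_size: int = 128
    max_epochs: int = 30
    learning_rate: float = 1e-3
    patience: int = 5
    ensemble_size: int = 0  # 0 disables the bootstrap ensemble
    n_explain: int = 3      # test patients to produce effect reports for

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = config_to_dict(self.sim)
        d["split_fractions"] = list(self.split_fractions)
        d["ffn_hidden"] = list(self.ffn_hidden)
        return d


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns a summary dict (also written to
    ``summary.json`` in the artifact directory). Idempotent given seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_dict())
    stamp = {"tool_version": __version__, "config_hash": chash,
             "seed": config.seed}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, f"{e} (config hash {chash})") from e
        return deco

    summary = {**stamp, "stages": {}}

    # -- cohort
    if config.cohort_path is None:
        config.sim.seed = config.seed
        records, truth = stage("simulate")(lambda: generate_cohort(config.sim))
        write_cohort(records, out / "cohort.jsonl")
        truth.save(out / "truth.json")
    else:
        records, rejects = stage("ingest")(
            lambda: read_cohort(config.cohort_path, out / "rejects.jsonl")
        )
        summary["stages"]["ingest"] = {"n_rejected": len(rejects)}
    summary["stages"]["cohort"] = {"n_records": len(records)}

    # -- exclusions
    kept, excluded = stage("exclusions")(lambda: apply_exclusions(records))
    with open(out / "exclusions.json", "w") as fh:
        json.dump([{"patient_id": p, "reason": r} for p, r in excluded], fh)
    summary["stages"]["exclusions"] = {
        "n_kept": len(kept), "n_exclusion_reasons": len(excluded)
    }

    # -- dictionary
    dictionary = stage("dictionary")(
        lambda: build_dictionary(kept, config.min_frequency, config.max_set_size)
    )
    dictionary.save(out / "dictionary.json")
    dict_hash = config_hash(dictionary.to_json())
    summary["stages"]["dictionary"] = {"n_codes": len(dictionary),
                                       "hash": dict_hash}

    # -- split / schema / augmentation
    train_r, val_r, test_r = stage("split")(
        lambda: split_cohort(kept, config.split_fractions, config.seed)
    )
    schema = stage("schema")(lambda: FeatureSchema.fit(train_r))
    (out / "schema.json").write_text(schema.to_json())
    train_aug = augment_training(train_r)
    summary["stages"]["split"] = {
        "n_train": len(train_r), "n_val": len(val_r), "n_test": len(test_r),
        "n_train_augmented": len(train_aug),
    }

    # -- fit
    model_config = ModelConfig(
        vocab_size=len(dictionary), feature_dim=schema.dim,
        embed_dim=config.embed_dim, max_set_size=config.max_set_size,
        n_heads=config.n_heads, ffn_hidden=config.ffn_hidden,
        dropout=config.dropout, objective=config.objective,
        init_seed=config.seed,
    )
    train_config = TrainConfig(
        batch_size=config.batch_size, max_epochs=config.max_epochs,
        learning_rate=config.learning_rate, patience=config.patience,
        seed=config.seed, objective=config.objective,
    )
    train_data = encode_cohort(train_aug, dictionary, schema)
    val_data = encode_cohort(val_r, dictionary, schema)
    model, log = stage("fit")(
        lambda: fit(train_data, val_data, model_config, train_config)
    )
    model.save(out / "model.npz", metadata={**stamp, "dict_hash": dict_hash,
                                            "schema": schema.to_json()})
    import csv as _csv
    with open(out / "training_log.csv", "w", newline="") as fh:
        w = _csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss",
                                            "selected"])
        w.writeheader()
        w.writerows(log)
    summary["stages"]["fit"] = {"selected_epoch": max(
        (r["epoch"] for r in log if r["selected"]), default=-1),
        "best_val_loss": min(r["val_loss"] for r in log)}

    # -- ensemble
    ensemble = []
    if config.ensemble_size >= 2:
        ensemble = stage("ensemble")(
            lambda: ensemble_fit(train_r, val_r, dictionary, schema,
                                 model_config, train_config,
                                 B=config.ensemble_size, seed=config.seed)
        )
        ens_dir = out / "ensemble"
        ens_dir.mkdir(exist_ok=True)
        for i, m in enumerate(ensemble):
            m["model"].save(ens_dir / f"member_{i}.npz",
                            metadata={**stamp, "dict_hash": dict_hash,
                                      "member_seed": m["seed"],
                                      "resample_indices": m["resample_indices"].tolist()})
        summary["stages"]["ensemble"] = {"B": len(ensemble)}

    # -- evaluate on the (never augmented) test split
    test_data = encode_cohort(test_r, dictionary, schema)
    pred = model.predict(test_data["indices"], test_data["mask"],
                         test_data["feats"])
    report = stage("evaluate")(
        lambda: evaluate_predictions(pred, test_data["y"], test_data["avail"],
                                     objective=config.objective,
                                     bootstrap_B=200, seed=config.seed)
    )
    report.to_frame().to_json(out / "eval_report.json", orient="records",
                              indent=1)
    summary["stages"]["evaluate"] = {
        d.day: {"n": d.n, "rmse": d.rmse, "auc4": d.auc4, "auc6": d.auc6}
        for d in report.days
    }

    # -- explain a few test patients
    reports = []
    for rec in test_r[: config.n_explain]:
        if not rec.codes:
            continue
        reports.append(stage("explain")(
            lambda rec=rec: explain_patient(model, ensemble, dictionary,
                                            schema, rec)
        ))
    with open(out / "code_effect_reports.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1)
    summary["stages"]["explain"] = {"n_reports": len(reports)}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary


def load_model_checked(model_path, dictionary: CodeDictionary) -> PopsModel:
    """Load a checkpoint and refuse to score inputs preprocessed under a
    different dictionary (hash mismatch)."""
    model, meta = PopsModel.load(model_path)
    expect = meta.get("dict_hash")
    actual = config_hash(dictionary.to_json())
    if expect is not None and expect != actual:
        raise ValueError(
            f"dictionary hash mismatch: model trained under {expect}, "
            f"inputs indexed under {actual}"
        )
    return model
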