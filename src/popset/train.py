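"""Model fitting: masked objectives, mini-batch Adam, validation-based
epoch selection, and bootstrap model ensembles for confidence intervals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import CodeDictionary, index_codes
from .features import FeatureSchema
from .model import ModelConfig, PopsModel
from .records import N_DAYS, build_outcomes
from .splits import augment_training


@dataclass
class TrainConfig:
    batch_size: int = 128
    max_epochs: int = 50
    learning_rate: float = 1e-3
    patience: int = 5
    seed: int = 0
    objective: str = "continuous"

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def encode_cohort(
    records, dictionary: CodeDictionary, schema: FeatureSchema
) -> dict[str, np.ndarray]:
    """Model-ready tensors for a list of records.

    Returns indices (N, S), present mask, feature matrix, per-day maximum
    pain with availability mask, and patient ids (kept for leakage checks).
    """
    n = len(records)
    S = dictionary.max_set_size
    indices = np.zeros((n, S), dtype=np.int64)
    mask = np.zeros((n, S), dtype=bool)
    y = np.full((n, N_DAYS), np.nan)
    avail = np.zeros((n, N_DAYS), dtype=bool)
    dropped = 0
    for i, rec in enumerate(records):
        idx, m, nd = index_codes(rec, dictionary)
        indices[i], mask[i] = idx, m
        dropped += nd
        out = build_outcomes(rec)
        y[i], avail[i] = out.max_pain, out.available
    feats = schema.transform_many(records)
    return {
        "indices": indices,
        "mask": mask,
        "feats": feats,
        "y": y,
        "avail": avail,
        "patient_ids": [r.patient_id for r in records],
        "n_codes_dropped": dropped,
    }


def masked_loss(pred: np.ndarray, max_pain: np.ndarray, avail: np.ndarray,
                objective: str) -> float:
    """Objective value on inference-scale predictions, masked to available
    days: mean squared error (continuous) or binary cross-entropy against
    the binarized outcome. Patients contribute only their available days;
    an all-unavailable input scores 0.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    max_pain = np.atleast_2d(np.asarray(max_pain, dtype=float))
    avail = np.atleast_2d(np.asarray(avail, dtype=bool))
    n_cells = avail.sum()
    if n_cells == 0:
        return 0.0
    y = np.where(avail, np.nan_to_num(max_pain), 0.0)
    if objective == "continuous":
        return float((((pred - y) ** 2) * avail).sum() / n_cells)
    threshold = int(objective.split("@")[1])
    t = (y > threshold).astype(float)
    eps = 1e-12
    ll = t * np.log(pred + eps) + (1 - t) * np.log(1 - pred + eps)
    return float(-(ll * avail).sum() / n_cells)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        params["E"][0] = 0.0  # keep the pad row zero


def _init_output_bias(model: PopsModel, train_data: dict) -> None:
    """Start the output layer at the per-day target mean (continuous) or
    the logit of the per-day event rate (binary), so the initial model is
    the population-mean predictor and optimization only has to learn
    structure on top of it."""
    y, avail = train_data["y"], train_data["avail"]
    last = model.n_ffn_layers - 1
    bias = np.zeros(N_DAYS)
    for d in range(N_DAYS):
        yd = y[avail[:, d], d]
        if yd.size == 0:
            continue
        if model.config.objective == "continuous":
            bias[d] = yd.mean()
        else:
            rate = np.clip((yd > model.config.threshold).mean(), 1e-3, 1 - 1e-3)
            bias[d] = np.log(rate / (1 - rate))
    model.params[f"b{last}"] = bias


def _val_loss(model: PopsModel, data: dict) -> float:
    loss, _ = model.loss_and_grads(
        data["indices"], data["mask"], data["feats"], data["y"], data["avail"],
        train=False,
    )
    return loss


def fit(
    train_data: dict,
    val_data: dict,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[PopsModel, list[dict]]:
    """Mini-batch Adam with per-epoch validation and early stopping.

    The checkpoint with lowest validation loss is kept ("the validation set
    was used for model selection"); training stops after ``patience``
    epochs without improvement. Fully reproducible given the seed.
    """
    train_config.validate()
    if len(train_data["patient_ids"]) == 0:
        raise ValueError("empty training set")
    model_config.objective = train_config.objective
    model = PopsModel(model_config)
    _init_output_bias(model, train_data)
    opt = _Adam(model.params, train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    N = train_data["indices"].shape[0]
    best_loss, best_params, best_epoch = np.inf, None, -1
    log: list[dict] = []
    for epoch in range(train_config.max_epochs):
        perm = rng.permutation(N)
        epoch_losses = []
        for start in range(0, N, train_config.batch_size):
            b = perm[start : start + train_config.batch_size]
            loss, grads = model.loss_and_grads(
                train_data["indices"][b],
                train_data["mask"][b],
                train_data["feats"][b],
                train_data["y"][b],
                train_data["avail"][b],
                dropout_rng=rng,
                train=True,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            epoch_losses.append(loss)
            opt.step(model.params, grads)
        vloss = _val_loss(model, val_data)
        improved = vloss < best_loss - 1e-12
        if improved:
            best_loss = vloss
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_epoch = epoch
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": float(vloss),
                "selected": bool(improved),
            }
        )
        if epoch - best_epoch >= train_config.patience:
            break
    model.params = best_params
    return model, log


def ensemble_fit(
    train_records,
    val_records,
    dictionary: CodeDictionary,
    schema: FeatureSchema,
    model_config: ModelConfig,
    train_config: TrainConfig,
    B: int,
    seed: int = 0,
) -> list[dict]:
    """B models fitted on nonparametric bootstrap resamples of the training
    patients (resample with replacement, then augment, then fit).

    Returns one entry per member: the fitted model, its resample indices,
    and its derived seed. Used for the bootstrap confidence intervals on
    model-dependent quantities.
    """
    if B < 2:
        raise ValueError("ensemble needs B >= 2 members")
    children = np.random.SeedSequence(seed).spawn(B)
    val_data = encode_cohort(val_records, dictionary, schema)
    members = []
    for b, child in enumerate(children):
        member_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(member_seed)
        idx = rng.integers(0, len(train_records), size=len(train_records))
        resampled = [train_records[i] for i in idx]
        augmented = augment_training(resampled)
        train_data = encode_cohort(augmented, dictionary, schema)
        mc = ModelConfig(**{**model_config.__dict__, "init_seed": member_seed})
        tc = TrainConfig(**{**train_config.__dict__, "seed": member_seed})
        model, log = fit(train_data, val_data, mc, tc)
        members.append({"model": model, "resample_indices": idx,
                        "seed": member_seed, "log": log})
    return members


def predict_records(model: PopsModel, records, dictionary, schema) -> np.ndarray:
    """Convenience: inference-scale predictions for raw records."""
    data = encode_cohort(records, dictionary, schema)
    return model.predict(data["indices"], data["mask"], data["feats"])
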