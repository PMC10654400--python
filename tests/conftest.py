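import numpy as np
import pytest

import popset
from popset.features import FeatureSchema
from popset.model import ModelConfig
from popset.splits import augment_training, split_cohort
from popset.train import TrainConfig, encode_cohort, ensemble_fit, fit


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap 300-patient cohort under default study conditions."""
    cfg = popset.SimConfig(n_patients=300, seed=11)
    records, truth = popset.generate_cohort(cfg)
    return records, truth, cfg


@pytest.fixture(scope="session")
def planted_setup():
    """Noise-free cohort with one ICD code planted at +2 NRS on all days,
    plus a continuous model fitted on it. Shared by the recovery tests."""
    cfg = popset.SimConfig(
        n_patients=2000,
        effect_codes={"ICD-0001": (2, 2, 2, 2, 2)},
        noise_sd=0.0,
        obs_noise_sd=0.0,
        pain_string_fraction=0.0,
        icu_rate=0.0,
        death_rate=0.0,
        seed=7,
    )
    records, truth = popset.generate_cohort(cfg)
    kept, _ = popset.apply_exclusions(records)
    dictionary = popset.build_dictionary(kept, 1e-4, 20)
    train_r, val_r, test_r = split_cohort(kept, seed=7)
    schema = FeatureSchema.fit(train_r)
    model_config = ModelConfig(
        vocab_size=len(dictionary), feature_dim=schema.dim, embed_dim=32,
        max_set_size=20, n_heads=4, ffn_hidden=(64, 32), dropout=0.1,
        objective="continuous", init_seed=7,
    )
    train_config = TrainConfig(batch_size=128, max_epochs=40,
                               learning_rate=3e-3, patience=6, seed=7)
    train_data = encode_cohort(augment_training(train_r), dictionary, schema)
    val_data = encode_cohort(val_r, dictionary, schema)
    model, log = fit(train_data, val_data, model_config, train_config)
    return {
        "records": kept, "truth": truth, "dictionary": dictionary,
        "schema": schema, "model": model, "log": log,
        "train": train_r, "val": val_r, "test": test_r,
        "train_data": train_data, "val_data": val_data,
        "model_config": model_config, "train_config": train_config,
        "code": "ICD-0001",
    }


@pytest.fixture(scope="session")
def small_ensemble():
    """Tiny bootstrap ensemble (B=3) on a small planted cohort, for the
    confidence-interval machinery."""
    cfg = popset.SimConfig(
        n_patients=400, effect_codes={"ICD-0001": (2, 2, 2, 2, 2)},
        noise_sd=0.5, icu_rate=0.0, death_rate=0.0, seed=13,
    )
    records, _ = popset.generate_cohort(cfg)
    kept, _ = popset.apply_exclusions(records)
    dictionary = popset.build_dictionary(kept, 1e-4, 20)
    train_r, val_r, _ = split_cohort(kept, seed=13)
    schema = FeatureSchema.fit(train_r)
    model_config = ModelConfig(
        vocab_size=len(dictionary), feature_dim=schema.dim, embed_dim=16,
        max_set_size=20, n_heads=2, ffn_hidden=(32, 16), dropout=0.0,
        objective="continuous", init_seed=13,
    )
    train_config = TrainConfig(batch_size=128, max_epochs=8,
                               learning_rate=3e-3, patience=4, seed=13)
    members = ensemble_fit(train_r, val_r, dictionary, schema, model_config,
                           train_config, B=3, seed=13)
    return {
        "members": members, "dictionary": dictionary, "schema": schema,
        "records": kept, "train": train_r, "val": val_r,
        "model_config": model_config, "train_config": train_config,
    }


@pytest.fixture
def tiny_model():
    """Untrained small model plus a valid random batch."""
    rng = np.random.default_rng(3)
    mc = ModelConfig(vocab_size=30, feature_dim=4, embed_dim=16,
                     max_set_size=8, n_heads=4, ffn_hidden=(12, 6),
                     dropout=0.0, objective="continuous", init_seed=3)
    model = popset.PopsModel(mc)
    B, S = 6, 8
    indices = np.zeros((B, S), dtype=np.int64)
    mask = np.zeros((B, S), dtype=bool)
    for i, n in enumerate([3, 1, 8, 0, 5, 2]):
        idx = rng.choice(np.arange(1, 31), size=n, replace=False)
        indices[i, :n] = idx
        mask[i, :n] = True
    feats = rng.normal(size=(B, 4))
    y = rng.uniform(0, 10, size=(B, 5))
    avail = rng.random((B, 5)) < 0.7
    avail[3] = False
    return model, {"indices": indices, "mask": mask, "feats": feats,
                   "y": y, "avail": avail}
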