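"""Network contracts: permutation/padding invariance, empty-set behavior,
attention-weight normalization, gradient correctness and flow, and
checkpoint round-trips."""

import numpy as np
import pytest

from popset.model import ModelConfig, PopsModel


def permute_batch(indices, mask, rng):
    out_idx = indices.copy()
    out_mask = mask.copy()
    for i in range(indices.shape[0]):
        n = int(mask[i].sum())
        if n > 1:
            perm = rng.permutation(n)
            out_idx[i, :n] = indices[i, :n][perm]
    return out_idx, out_mask


def test_forward_outputs_five_days(tiny_model):
    model, batch = tiny_model
    out, _ = model.forward(batch["indices"], batch["mask"], batch["feats"])
    assert out.shape == (batch["indices"].shape[0], 5)


def test_binary_mode_outputs_probabilities(tiny_model):
    model, batch = tiny_model
    model.config.objective = "binary@4"
    p = model.predict(batch["indices"], batch["mask"], batch["feats"])
    assert ((p > 0) & (p < 1)).all()


def test_continuous_predictions_clamped(tiny_model):
    model, batch = tiny_model
    # blow up a weight so raw outputs leave [0, 10]
    model.params["b2"] += 100.0
    p = model.predict(batch["indices"], batch["mask"], batch["feats"])
    assert p.max() <= 10.0 and p.min() >= 0.0


def test_permutation_invariance_of_predictions(tiny_model):
    model, batch = tiny_model
    rng = np.random.default_rng(0)
    base = model.predict(batch["indices"], batch["mask"], batch["feats"])
    for _ in range(5):
        idx, mask = permute_batch(batch["indices"], batch["mask"], rng)
        out = model.predict(idx, mask, batch["feats"])
        np.testing.assert_allclose(out, base, rtol=1e-6, atol=1e-9)


def test_padding_invariance(tiny_model):
    model, batch = tiny_model
    base = model.predict(batch["indices"], batch["mask"], batch["feats"])
    wide = ModelConfig(**{**model.config.__dict__, "max_set_size": 18})
    wide_model = PopsModel(wide)
    wide_model.params = {k: v.copy() for k, v in model.params.items()}
    B, S = batch["indices"].shape
    idx = np.zeros((B, 18), dtype=np.int64)
    mask = np.zeros((B, 18), dtype=bool)
    idx[:, :S] = batch["indices"]
    mask[:, :S] = batch["mask"]
    out = wide_model.predict(idx, mask, batch["feats"])
    np.testing.assert_allclose(out, base, rtol=1e-6, atol=1e-9)


def test_empty_set_pools_to_zero_vector(tiny_model):
    model, batch = tiny_model
    X = model.embed_codes(batch["indices"][[3]])
    pooled, _, _ = model.attend_and_pool(X, batch["mask"][[3]])
    np.testing.assert_array_equal(pooled, 0.0)


def test_embedding_matrix_zero_padded(tiny_model):
    model, batch = tiny_model
    X = model.embed_codes(batch["indices"])
    assert np.all(X[~batch["mask"]] == 0.0)  # pad rows are the zero row
    assert np.all(np.abs(X[batch["mask"]]).sum(axis=-1) > 0)


def test_embedding_rejects_out_of_range_index(tiny_model):
    model, batch = tiny_model
    bad = batch["indices"].copy()
    bad[0, 0] = model.config.vocab_size + 5
    with pytest.raises(IndexError):
        model.embed_codes(bad)


def test_attention_weights_sum_to_one_and_single_code_gets_all(tiny_model):
    model, batch = tiny_model
    present = batch["mask"].any(axis=1)
    w = model.attention_weights(batch["indices"][present], batch["mask"][present])
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)
    single = np.where(batch["mask"].sum(axis=1) == 1)[0]
    assert w[(batch["mask"][present].sum(axis=1) == 1)].max() == pytest.approx(1.0)


def test_attention_weights_error_on_empty_set(tiny_model):
    model, batch = tiny_model
    with pytest.raises(ValueError):
        model.attention_weights(batch["indices"][[3]], batch["mask"][[3]])


def test_gradients_match_finite_differences(tiny_model):
    model, batch = tiny_model
    rng = np.random.default_rng(1)
    for objective in ("continuous", "binary@6"):
        model.config.objective = objective
        loss, grads = model.loss_and_grads(
            batch["indices"], batch["mask"], batch["feats"],
            batch["y"], batch["avail"], train=False)
        eps = 1e-5
        for k, P in model.params.items():
            flat = P.ravel()
            for j in rng.choice(flat.size, size=min(10, flat.size), replace=False):
                old = flat[j]
                flat[j] = old + eps
                lp, _ = model.loss_and_grads(
                    batch["indices"], batch["mask"], batch["feats"],
                    batch["y"], batch["avail"], train=False)
                flat[j] = old - eps
                lm, _ = model.loss_and_grads(
                    batch["indices"], batch["mask"], batch["feats"],
                    batch["y"], batch["avail"], train=False)
                flat[j] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[k].ravel()[j]) < 1e-6 * max(1, abs(num)), k


def test_gradient_flow_present_codes_only(tiny_model):
    model, batch = tiny_model
    _, grads = model.loss_and_grads(
        batch["indices"], batch["mask"], batch["feats"],
        batch["y"], batch["avail"], train=False)
    present = set(batch["indices"][batch["mask"]].tolist())
    absent = set(range(model.config.vocab_size + 1)) - present
    gE = grads["E"]
    assert all(np.abs(gE[i]).sum() > 0 for i in present)
    assert all(np.abs(gE[i]).sum() == 0 for i in absent)
    assert np.abs(gE[0]).sum() == 0  # pad row never updates


def test_checkpoint_round_trip_bitwise(tmp_path, tiny_model):
    model, batch = tiny_model
    base = model.predict(batch["indices"], batch["mask"], batch["feats"])
    path = tmp_path / "model.npz"
    model.save(path, metadata={"dict_hash": "abc"})
    loaded, meta = PopsModel.load(path)
    assert meta["dict_hash"] == "abc"
    out = loaded.predict(batch["indices"], batch["mask"], batch["feats"])
    assert np.array_equal(out, base)  # bitwise identical


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(vocab_size=5, feature_dim=2, embed_dim=10, n_heads=4).validate()
    with pytest.raises(ValueError):
        ModelConfig(vocab_size=5, feature_dim=2, objective="nope").validate()
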