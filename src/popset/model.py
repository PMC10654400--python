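"""The POPS network: permutation-invariant set embedding of a patient's
CPT/ICD-10 code set, fused with structured features, predicting maximum
pain on postoperative days 0-4.

Architecture (all sizes configurable; defaults follow the reference
design): an embedding table maps the indexed code set to a zero-padded
``max_set_size x embed_dim`` matrix (130 x 256 by default; index 0 is the
all-zero pad row). A masked multi-head self-attention layer mixes the code
embeddings — pad slots are excluded from the softmax by additive -inf
logits, and no positional information is used, so the layer is exactly
permutation-invariant. Mean pooling over the *present* positions yields the
256-d set embedding (an empty code set yields the zero vector). The set
embedding is concatenated with the normalized structured-feature vector and
passed through a ReLU feed-forward network with five linear outputs, one
per postoperative day. Binary objectives (pain > 4, pain > 6) apply a
logistic link; the continuous objective clamps predictions to [0, 10] at
inference only, so training gradients are unbiased.

Implemented directly in NumPy with hand-written reverse-mode gradients
(verified against finite differences in the test suite); the model is small
enough that CPU matrix products are entirely adequate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .records import N_DAYS

OBJECTIVES = ("continuous", "binary@4", "binary@6")
CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    vocab_size: int  # number of real codes; table has vocab_size+1 rows
    feature_dim: int
    embed_dim: int = 256
    max_set_size: int = 130
    n_heads: int = 4
    ffn_hidden: tuple = (256, 128)
    dropout: float = 0.1
    objective: str = "continuous"
    init_seed: int = 0

    def validate(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0,1)")

    @property
    def threshold(self) -> int | None:
        """Binarization threshold for binary objectives, else None."""
        if self.objective.startswith("binary@"):
            return int(self.objective.split("@")[1])
        return None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class PopsModel:
    """Set-embedding pain-prediction model with explicit parameters.

    Parameters are float64 NumPy arrays in ``self.params``; the pad row of
    the embedding table (index 0) is pinned to zero so that padding can
    never leak into the pooled representation.
    """

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        D, F = config.embed_dim, config.feature_dim
        V = config.vocab_size
        h_sizes = [D + F, *config.ffn_hidden, N_DAYS]

        def xavier(n_in, n_out):
            bound = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-bound, bound, size=(n_in, n_out))

        self.params: dict[str, np.ndarray] = {
            "E": rng.normal(0.0, 0.1, size=(V + 1, D)),
            "Wq": xavier(D, D),
            "Wk": xavier(D, D),
            "Wv": xavier(D, D),
            "Wo": xavier(D, D),
        }
        self.params["E"][0] = 0.0  # pad row stays zero
        for i in range(len(h_sizes) - 1):
            self.params[f"W{i}"] = xavier(h_sizes[i], h_sizes[i + 1])
            self.params[f"b{i}"] = np.zeros(h_sizes[i + 1])
        self.n_ffn_layers = len(h_sizes) - 1

    # ---------------------------------------------------------------- forward

    def embed_codes(self, indices: np.ndarray) -> np.ndarray:
        """Zero-padded (max_set_size x embed_dim) matrix per patient.

        ``indices`` is (B, S) int with 0 for pad slots; row 0 of the table
        is identically zero, so pad slots map to zero rows.
        """
        indices = np.asarray(indices)
        if indices.max(initial=0) > self.config.vocab_size or indices.min(initial=0) < 0:
            raise IndexError("code index outside the dictionary range")
        return self.params["E"][indices]

    def attend_and_pool(
        self, X: np.ndarray, mask: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, dict]:
        """Masked multi-head self-attention followed by mean pooling.

        Returns ``(pooled, attn, cache)`` with ``pooled`` (B, D), ``attn``
        (B, H, S, S) post-softmax attention (pad keys carry zero weight for
        non-empty sets), and a cache of intermediates for backprop. Empty
        sets pool to the zero vector.
        """
        cfg = self.config
        B, S, D = X.shape
        H = cfg.n_heads
        dh = D // H
        mask = np.asarray(mask, dtype=bool)

        def heads(M):  # (B,S,D) -> (B,H,S,dh)
            return M.reshape(B, S, H, dh).transpose(0, 2, 1, 3)

        Q = heads(X @ self.params["Wq"])
        K = heads(X @ self.params["Wk"])
        V = heads(X @ self.params["Wv"])
        scores = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(dh)
        neg = np.where(mask, 0.0, -1e9)  # additive mask on the key axis
        scores = scores + neg[:, None, None, :]
        scores -= scores.max(axis=-1, keepdims=True)
        exps = np.exp(scores)
        A = exps / exps.sum(axis=-1, keepdims=True)
        O = (A @ V).transpose(0, 2, 1, 3).reshape(B, S, D)
        Y = O @ self.params["Wo"]
        counts = mask.sum(axis=1)
        denom = np.maximum(counts, 1)[:, None].astype(float)
        pooled = (Y * mask[:, :, None]).sum(axis=1) / denom
        cache = {"X": X, "Q": Q, "K": K, "V": V, "A": A, "O": O, "Y": Y,
                 "mask": mask, "denom": denom}
        return pooled, A, cache

    def forward(
        self,
        indices: np.ndarray,
        mask: np.ndarray,
        feats: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Raw 5-day outputs (pre-link, pre-clamp) and the backprop cache."""
        if feats.shape[1] != self.config.feature_dim:
            raise ValueError(
                f"feature dim {feats.shape[1]} != schema dim {self.config.feature_dim}"
            )
        X = self.embed_codes(indices)
        pooled, A, att_cache = self.attend_and_pool(X, mask)
        z = np.concatenate([pooled, feats], axis=1)
        cache = {"indices": indices, "att": att_cache, "z": z, "A": A,
                 "acts": [], "pres": [], "drops": []}
        h = z
        p_drop = self.config.dropout if train else 0.0
        if p_drop > 0 and dropout_rng is None:
            dropout_rng = np.random.default_rng(0)
        for i in range(self.n_ffn_layers):
            pre = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            cache["pres"].append(pre)
            if i < self.n_ffn_layers - 1:
                h = np.maximum(pre, 0.0)
                if p_drop > 0:
                    keep = (dropout_rng.random(h.shape) >= p_drop) / (1 - p_drop)
                    h = h * keep
                    cache["drops"].append(keep)
                else:
                    cache["drops"].append(None)
            else:
                h = pre
            cache["acts"].append(h)
        return h, cache

    def predict(self, indices, mask, feats) -> np.ndarray:
        """Inference-scale predictions: NRS clamped to [0,10] (continuous)
        or event probabilities (binary objectives)."""
        out, _ = self.forward(indices, mask, feats, train=False)
        if self.config.objective == "continuous":
            return np.clip(out, 0.0, 10.0)
        return _sigmoid(out)

    def attention_weights(self, indices, mask, feats=None) -> np.ndarray:
        """Per-code attention weight: the post-softmax attention paid to
        each present code, averaged over heads and present query positions.

        Returns (B, S) weights; rows sum to 1 over present codes. Raises on
        an all-empty input (weights are undefined for an empty set).
        """
        mask = np.asarray(mask, dtype=bool)
        if not mask.any(axis=1).all():
            raise ValueError("attention weights undefined for an empty code set")
        X = self.embed_codes(indices)
        _, A, _ = self.attend_and_pool(X, mask)
        q_mask = mask[:, None, :, None]  # average only over present queries
        w = (A * q_mask).sum(axis=(1, 2)) / (
            self.config.n_heads * mask.sum(axis=1, keepdims=True)
        )
        return w * mask

    # --------------------------------------------------------------- backward

    def loss_and_grads(
        self,
        indices: np.ndarray,
        mask: np.ndarray,
        feats: np.ndarray,
        y: np.ndarray,
        avail: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
        train: bool = True,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Masked objective and gradients for one mini-batch.

        Continuous: mean squared error over available (patient, day) cells.
        Binary: cross-entropy against the binarized outcome over the same
        cells. Patients with no available day contribute nothing.
        """
        cfg = self.config
        out, cache = self.forward(indices, mask, feats, train=train,
                                  dropout_rng=dropout_rng)
        avail = np.asarray(avail, dtype=float)
        n_cells = max(avail.sum(), 1.0)
        y = np.asarray(y, dtype=float)
        y_safe = np.where(avail > 0, np.nan_to_num(y), 0.0)
        if cfg.objective == "continuous":
            resid = (out - y_safe) * avail
            loss = float((resid**2).sum() / n_cells)
            dout = 2.0 * resid / n_cells
        else:
            t = (y_safe > cfg.threshold).astype(float)
            p = _sigmoid(out)
            eps = 1e-12
            ll = t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)
            loss = float(-(ll * avail).sum() / n_cells)
            dout = (p - t) * avail / n_cells

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        # FFN backward
        dh = dout
        for i in reversed(range(self.n_ffn_layers)):
            inp = cache["z"] if i == 0 else cache["acts"][i - 1]
            grads[f"W{i}"] = inp.T @ dh
            grads[f"b{i}"] = dh.sum(axis=0)
            dinp = dh @ self.params[f"W{i}"].T
            if i > 0:
                keep = cache["drops"][i - 1]
                if keep is not None:
                    dinp = dinp * keep
                dinp = dinp * (cache["pres"][i - 1] > 0)
            dh = dinp
        D = cfg.embed_dim
        dpooled = dh[:, :D]

        # pooling backward
        att = cache["att"]
        mask_b = att["mask"]
        B, S, _ = att["X"].shape
        H = cfg.n_heads
        d_head = D // H
        dY = (dpooled / att["denom"])[:, None, :] * mask_b[:, :, None]

        # output projection
        grads["Wo"] = att["O"].reshape(-1, D).T @ dY.reshape(-1, D)
        dO = dY @ self.params["Wo"].T
        dO = dO.reshape(B, S, H, d_head).transpose(0, 2, 1, 3)  # (B,H,S,dh)

        A, V, Q, K = att["A"], att["V"], att["Q"], att["K"]
        dA = dO @ V.transpose(0, 1, 3, 2)
        dV = A.transpose(0, 1, 3, 2) @ dO
        # softmax jacobian, row-wise
        dS = A * (dA - (A * dA).sum(axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(d_head)
        dQ = dS @ K * scale
        dK = dS.transpose(0, 1, 3, 2) @ Q * scale

        def merge(M):  # (B,H,S,dh) -> (B,S,D)
            return M.transpose(0, 2, 1, 3).reshape(B, S, D)

        dQm, dKm, dVm = merge(dQ), merge(dK), merge(dV)
        X = att["X"]
        Xf = X.reshape(-1, D)
        grads["Wq"] = Xf.T @ dQm.reshape(-1, D)
        grads["Wk"] = Xf.T @ dKm.reshape(-1, D)
        grads["Wv"] = Xf.T @ dVm.reshape(-1, D)
        dX = (
            dQm @ self.params["Wq"].T
            + dKm @ self.params["Wk"].T
            + dVm @ self.params["Wv"].T
        )
        np.add.at(grads["E"], cache["indices"], dX)
        grads["E"][0] = 0.0  # pad row never updates
        return loss, grads

    # ------------------------------------------------------------ persistence

    def save(self, path, metadata: dict | None = None) -> None:
        """Versioned checkpoint: weights + config + arbitrary metadata
        (dictionary hash, feature schema, ...)."""
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": {**asdict(self.config),
                       "ffn_hidden": list(self.config.ffn_hidden)},
            "metadata": metadata or {},
        }
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        np.savez(path, meta_json=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> tuple["PopsModel", dict]:
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError("unsupported checkpoint format version")
            cfg_d = dict(meta["config"])
            cfg_d["ffn_hidden"] = tuple(cfg_d["ffn_hidden"])
            model = cls(ModelConfig(**cfg_d))
            for k in model.params:
                model.params[k] = z[f"param_{k}"].copy()
        return model, meta["metadata"]
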