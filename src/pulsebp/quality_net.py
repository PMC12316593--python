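"""Hybrid convolutional noise classifier (numpy implementation).

Architecture: two 1-D convolutional blocks over the z-scored 1000-sample
window — 16 filters of length 500 then 32 filters of length 250, each
followed by a rectifier and max-pool of size 2 (valid convolution, the
second block spans its whole input and so acts as a dense projection) —
whose output is concatenated with the eight hand-engineered quality
features and passed through a 32-unit rectified layer and a sigmoid
output.  Trained with cross-entropy via Adam; decision threshold 0.5.

No deep-learning framework is assumed: forward and backward passes are
written directly with numpy, which is ample for windows of this size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .quality import (
    N_HAND_FEATURES,
    WINDOW_N,
    fuse_segments,
    hand_feature_matrix,
    screen_hard_artifacts,
)

CONV1_FILTERS, CONV1_LEN = 16, 500
CONV2_FILTERS, CONV2_LEN = 32, 250
HEAD_UNITS = 32
_L1_OUT = WINDOW_N - CONV1_LEN + 1          # 501
_P1_OUT = _L1_OUT // 2                      # 250
_FLAT = _P1_OUT * CONV1_FILTERS             # conv2 input size


def _zscore_rows(X):
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


@dataclass
class HybridNoiseModel:
    weights: dict
    hand_mean: np.ndarray
    hand_std: np.ndarray
    threshold: float = 0.5
    seed: int = 0
    history: list = field(default_factory=list)

    @classmethod
    def init(cls, seed: int = 0) -> "HybridNoiseModel":
        rng = np.random.default_rng(seed)

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return rng.uniform(-lim, lim, shape).astype(np.float32)

        weights = {
            "W1": glorot((CONV1_LEN, CONV1_FILTERS)),
            "b1": np.zeros(CONV1_FILTERS, np.float32),
            "W2": glorot((_FLAT, CONV2_FILTERS)),
            "b2": np.zeros(CONV2_FILTERS, np.float32),
            "W3": glorot((CONV2_FILTERS + N_HAND_FEATURES, HEAD_UNITS)),
            "b3": np.zeros(HEAD_UNITS, np.float32),
            "W4": glorot((HEAD_UNITS, 1)),
            "b4": np.zeros(1, np.float32),
        }
        return cls(weights=weights,
                   hand_mean=np.zeros(N_HAND_FEATURES),
                   hand_std=np.ones(N_HAND_FEATURES),
                   seed=seed)

    # -- forward -----------------------------------------------------------
    def _forward(self, X, H, keep: bool = False):
        w = self.weights
        V = np.lib.stride_tricks.sliding_window_view(X, CONV1_LEN, axis=1)
        Z1 = V @ w["W1"] + w["b1"]                      # (B, 501, 16)
        A1 = np.maximum(Z1, 0.0)
        pairs = A1[:, :2 * _P1_OUT].reshape(len(X), _P1_OUT, 2, CONV1_FILTERS)
        which = pairs.argmax(axis=2)
        P1 = pairs.max(axis=2)                          # (B, 250, 16)
        F1 = P1.reshape(len(X), _FLAT)
        Z2 = F1 @ w["W2"] + w["b2"]                     # conv2 == dense here
        A2 = np.maximum(Z2, 0.0)                        # pool of a single step: identity
        Hs = (H - self.hand_mean) / self.hand_std
        F = np.concatenate([A2, Hs], axis=1)
        Z3 = F @ w["W3"] + w["b3"]
        A3 = np.maximum(Z3, 0.0)
        Z4 = A3 @ w["W4"] + w["b4"]
        p = 1.0 / (1.0 + np.exp(-Z4[:, 0]))
        if not keep:
            return p
        return p, {"V": V, "Z1": Z1, "which": which, "F1": F1, "Z2": Z2,
                   "F": F, "Z3": Z3, "A3": A3}

    def predict_proba(self, X: np.ndarray, H: np.ndarray) -> np.ndarray:
        """Noise probability per window; X (B,1000) raw samples, H (B,8)
        hand features."""
        X = _zscore_rows(np.asarray(X, np.float32))
        return self._forward(X, np.asarray(H, np.float32))

    def predict_noisy(self, X, H) -> np.ndarray:
        return self.predict_proba(X, H) >= self.threshold

    # -- persistence -------------------------------------------------------
    def save(self, path):
        np.savez(path, hand_mean=self.hand_mean, hand_std=self.hand_std,
                 threshold=self.threshold, seed=self.seed, **self.weights)

    @classmethod
    def load(cls, path) -> "HybridNoiseModel":
        data = np.load(path)
        weights = {k: data[k] for k in
                   ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")}
        return cls(weights=weights, hand_mean=data["hand_mean"],
                   hand_std=data["hand_std"],
                   threshold=float(data["threshold"]), seed=int(data["seed"]))


def train_noise_classifier(
    X: np.ndarray,
    H: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 64,
    lr: float = 1e-3,
    holdout: float = 0.2,
):
    """Train the hybrid model on labeled windows (y=1 noisy).

    80% of the corpus is used for training/validation and 20% held out;
    returns ``(model, metrics)`` where metrics holds held-out sensitivity
    and specificity.
    """
    X = np.asarray(X, np.float32)
    H = np.asarray(H, np.float32)
    y = np.asarray(y, np.float32)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes required to train the classifier")
    if X.shape[1] != WINDOW_N:
        raise InvalidInputError(f"windows must have {WINDOW_N} samples")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    n_test = int(round(holdout * len(X)))
    test_idx, train_idx = order[:n_test], order[n_test:]

    model = HybridNoiseModel.init(seed)
    model.hand_mean = H[train_idx].mean(axis=0)
    sd = H[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    model.hand_std = sd

    Xtr = _zscore_rows(X[train_idx])
    Htr = H[train_idx]
    ytr = y[train_idx]

    w = model.weights
    m = {k: np.zeros_like(v) for k, v in w.items()}
    v = {k: np.zeros_like(vv) for k, vv in w.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    for epoch in range(epochs):
        perm = rng.permutation(len(Xtr))
        losses = []
        for s in range(0, len(Xtr), batch_size):
            idx = perm[s:s + batch_size]
            xb, hb, yb = Xtr[idx], Htr[idx], ytr[idx]
            p, cache = model._forward(xb, hb, keep=True)
            p = np.clip(p, 1e-7, 1 - 1e-7)
            losses.append(float(-np.mean(yb * np.log(p) + (1 - yb) * np.log(1 - p))))

            B = len(xb)
            dZ4 = ((p - yb) / B)[:, None]
            grads = {}
            grads["W4"] = cache["A3"].T @ dZ4
            grads["b4"] = dZ4.sum(axis=0)
            dA3 = dZ4 @ w["W4"].T
            dZ3 = dA3 * (cache["Z3"] > 0)
            grads["W3"] = cache["F"].T @ dZ3
            grads["b3"] = dZ3.sum(axis=0)
            dF = dZ3 @ w["W3"].T
            dA2 = dF[:, :CONV2_FILTERS]
            dZ2 = dA2 * (cache["Z2"] > 0)
            grads["W2"] = cache["F1"].T @ dZ2
            grads["b2"] = dZ2.sum(axis=0)
            dF1 = dZ2 @ w["W2"].T
            dP1 = dF1.reshape(B, _P1_OUT, CONV1_FILTERS)
            dA1 = np.zeros((B, _L1_OUT, CONV1_FILTERS), np.float32)
            bi = np.arange(B)[:, None, None]
            pi = np.arange(_P1_OUT)[None, :, None]
            fi = np.arange(CONV1_FILTERS)[None, None, :]
            np.add.at(dA1, (bi, 2 * pi + cache["which"], fi), dP1)
            dZ1 = dA1 * (cache["Z1"] > 0)
            grads["W1"] = np.einsum("bos,bof->sf", cache["V"], dZ1,
                                    optimize=True).astype(np.float32)
            grads["b1"] = dZ1.sum(axis=(0, 1))

            step += 1
            for k in w:
                g = grads[k].astype(np.float32).reshape(w[k].shape)
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mh = m[k] / (1 - b1 ** step)
                vh = v[k] / (1 - b2 ** step)
                w[k] -= (lr * mh / (np.sqrt(vh) + eps)).astype(np.float32)
        model.history.append(float(np.mean(losses)))

    pt = model.predict_proba(X[test_idx], H[test_idx]) >= model.threshold
    yt = y[test_idx].astype(bool)
    tp = np.sum(pt & yt)
    tn = np.sum(~pt & ~yt)
    metrics = {
        "sensitivity": float(tp / max(1, yt.sum())),
        "specificity": float(tn / max(1, (~yt).sum())),
        "n_test": int(n_test),
    }
    return model, metrics


def classify_and_fuse(model: HybridNoiseModel, windows_per_channel: dict,
                      channel_kinds: dict) -> dict:
    """Label each channel's windows and fuse into segment verdicts.

    Hard screens win unconditionally: a window failing them is noisy no
    matter what the classifier says.  Returns per-channel clean flags,
    probabilities and the fused per-segment clean vector.
    """
    clean = {}
    probs = {}
    for name, wins in windows_per_channel.items():
        if not wins:
            clean[name] = np.zeros(0, dtype=bool)
            probs[name] = np.zeros(0)
            continue
        kind = channel_kinds[name]
        hard = np.array([any(screen_hard_artifacts(w, kind)) for w in wins])
        X = np.stack([w.samples for w in wins])
        H = hand_feature_matrix(wins, channel_kinds)
        p = model.predict_proba(X, H)
        noisy = hard | (p >= model.threshold)
        clean[name] = ~noisy
        probs[name] = p
    fused = fuse_segments(clean)
    return {"clean_per_channel": clean, "probability": probs, "segment_clean": fused}
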