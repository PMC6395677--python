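"""The patch classifier: a small CIFAR-10-style convolutional network.

Architecture (fixed strides, configurable widths): three blocks of
5x5 stride-1 'same' convolution -> ReLU -> 3x3 stride-2 ceil-mode max
pool, reducing a 32x32x3 input to 4x4x64, followed by a 64-wide fully
connected hidden layer (ReLU) and a 2-way softmax head.  Grayscale
patches are replicated into the three input channels and scaled to
[-0.5, 0.5] before entering the network.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np

from ..datatypes import ParameterError
from . import layers as L


@dataclass(frozen=True)
class ModelSpec:
    input_side: int = 32
    in_channels: int = 3
    conv_channels: tuple = (32, 32, 64)
    kernel: int = 5
    pool: int = 3
    pool_stride: int = 2
    hidden: int = 64
    n_classes: int = 2

    def __post_init__(self):
        if len(self.conv_channels) != 3:
            raise ParameterError("the architecture fixes three convolutional layers")
        if self.n_classes < 2:
            raise ParameterError("need at least two classes")
        side = self.input_side
        for _ in self.conv_channels:
            side = L.pool_out_len(side, self.pool, self.pool_stride)
        if side < 1:
            raise ParameterError("input too small for three pooling stages")

    @property
    def flat_features(self) -> int:
        side = self.input_side
        for _ in self.conv_channels:
            side = L.pool_out_len(side, self.pool, self.pool_stride)
        return side * side * self.conv_channels[-1]


class PatchClassifier:
    """Convolutional on-line/off-line patch classifier.

    Parameters live in ``self.params`` (He-initialized from one seed);
    ``self.log`` collects one entry per training epoch.
    """

    WEIGHT_KEYS = ("W1", "W2", "W3", "W4", "W5")

    def __init__(self, spec: ModelSpec = None, seed: int = 0, dtype=np.float32):
        self.spec = spec or ModelSpec()
        self.dtype = np.dtype(dtype)
        self.log = []
        self.fingerprint = {}
        rng = np.random.default_rng(seed)
        s = self.spec
        k = s.kernel
        chans = (s.in_channels,) + tuple(s.conv_channels)
        p = {}
        for i in range(3):
            fan_in = chans[i] * k * k
            p[f"W{i+1}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (k, k, chans[i], chans[i + 1])
            )
            p[f"b{i+1}"] = np.zeros(chans[i + 1])
        p["W4"] = rng.normal(
            0.0, np.sqrt(2.0 / s.flat_features), (s.flat_features, s.hidden)
        )
        p["b4"] = np.zeros(s.hidden)
        p["W5"] = rng.normal(0.0, 0.01, (s.hidden, s.n_classes))
        p["b5"] = np.zeros(s.n_classes)
        self.params = {key: v.astype(self.dtype) for key, v in p.items()}

    # ---- input handling -------------------------------------------------

    def prepare(self, x) -> np.ndarray:
        """Accept (N,side,side) grayscale or (N,side,side,C); return the
        normalized NHWC float tensor fed to the network."""
        x = np.asarray(x)
        side, c = self.spec.input_side, self.spec.in_channels
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            if x.shape[1:] != (side, side):
                raise ParameterError(
                    f"patch must be {side}x{side}, got {x.shape[1:]}"
                )
            x = np.repeat(x[..., None], c, axis=3)
        elif x.ndim == 4:
            if x.shape[1:] != (side, side, c):
                raise ParameterError(
                    f"input must be (N,{side},{side},{c}), got {x.shape}"
                )
        else:
            raise ParameterError(f"cannot interpret input of shape {x.shape}")
        return x.astype(self.dtype) / 255.0 - 0.5

    # ---- forward / backward ---------------------------------------------

    def forward(self, x, need_cache=False):
        """x: normalized NHWC (N,side,side,C) tensor -> (logits, caches)."""
        p = self.params
        s = self.spec
        caches = []
        h = x
        for i in (1, 2, 3):
            h, cc = L.conv_forward(h, p[f"W{i}"], p[f"b{i}"], need_cache)
            h, rm = L.relu_forward(h)
            h, pc = L.maxpool_forward(h, s.pool, s.pool_stride)
            caches.append((cc, rm, pc))
        n = h.shape[0]
        flat = h.reshape(n, -1)
        h4, c4 = L.dense_forward(flat, p["W4"], p["b4"])
        a4, r4 = L.relu_forward(h4)
        logits, c5 = L.dense_forward(a4, p["W5"], p["b5"])
        caches.append((h.shape, c4, r4, c5))
        return logits, caches

    def backward(self, dlogits, caches):
        """Gradient of the data term w.r.t. every parameter."""
        p = self.params
        grads = {}
        pool_shape, c4, r4, c5 = caches[-1]
        da4, grads["W5"], grads["b5"] = L.dense_backward(dlogits, c5)
        dh4 = L.relu_backward(da4, r4)
        dflat, grads["W4"], grads["b4"] = L.dense_backward(dh4, c4)
        dh = dflat.reshape(pool_shape)
        for i in (3, 2, 1):
            cc, rm, pc = caches[i - 1]
            dh = L.maxpool_backward(dh, pc)
            dh = L.relu_backward(dh, rm)
            # the input gradient of the first conv is never consumed
            dh, grads[f"W{i}"], grads[f"b{i}"] = L.conv_backward(
                dh, cc, need_dx=(i > 1)
            )
        return grads

    # ---- inference -------------------------------------------------------

    def predict_proba(self, patches, batch_size: int = 64) -> np.ndarray:
        """Class probabilities, chunked so im2col buffers stay small."""
        x = self.prepare(patches)
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits, _ = self.forward(x[i : i + batch_size])
            out.append(L.softmax(logits))
        return np.concatenate(out) if out else np.zeros((0, self.spec.n_classes))

    def predict(self, patches, batch_size: int = 64):
        """(labels, probabilities); label 1 only when p(1) strictly exceeds
        p(0), so ties resolve to the off-line class."""
        probs = self.predict_proba(patches, batch_size)
        labels = (probs[:, 1] > probs[:, 0]).astype(np.int64)
        return labels, probs

    # ---- persistence -----------------------------------------------------

    def save(self, model_dir) -> None:
        os.makedirs(model_dir, exist_ok=True)
        np.savez(os.path.join(model_dir, "params.npz"), **self.params)
        meta = {
            "spec": dataclasses.asdict(self.spec),
            "dtype": self.dtype.name,
            "fingerprint": self.fingerprint,
            "log": self.log,
        }
        from .._util import atomic_write_text

        atomic_write_text(
            os.path.join(model_dir, "model.json"), json.dumps(meta, indent=2)
        )

    @classmethod
    def load(cls, model_dir) -> "PatchClassifier":
        with open(os.path.join(model_dir, "model.json")) as fh:
            meta = json.load(fh)
        spec_d = meta["spec"]
        spec_d["conv_channels"] = tuple(spec_d["conv_channels"])
        model = cls(ModelSpec(**spec_d), dtype=np.dtype(meta["dtype"]))
        with np.load(os.path.join(model_dir, "params.npz")) as data:
            model.params = {k: data[k].astype(model.dtype) for k in data.files}
        model.fingerprint = meta.get("fingerprint", {})
        model.log = meta.get("log", [])
        return model
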