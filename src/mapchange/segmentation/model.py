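"""Compact U-Net with a configurable-width encoder.

Three resolution levels with skip connections: enough receptive field
(tens of pixels) to read areal textures such as mire hatching, yet small
enough to train on one CPU. The backbone string selects the base width:
``"unet8"``, ``"unet16"`` (default) or ``"unet32"``.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from .nn import Conv2D, MaxPool2, Param, ReLU, Upsample2

__all__ = ["UNet", "build_model", "N_CLASSES"]

N_CLASSES = 6  # background + five map classes

_BACKBONES = {"unet8": 8, "unet16": 16, "unet32": 32}


class _ConvBlock:
    """conv3x3 + ReLU (+ optional second conv)."""

    def __init__(self, c_in, c_out, rng, double=False):
        self.layers = [Conv2D(c_in, c_out, 3, rng), ReLU()]
        if double:
            self.layers += [Conv2D(c_out, c_out, 3, rng), ReLU()]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet:
    """3-level encoder-decoder over RGB tiles, ``N_CLASSES`` logits out.

    The encoder (the "backbone") can be frozen for warm-up epochs, after
    which all weights train — mirroring the frozen/unfrozen fine-tuning
    schedule used with pretrained backbones at full scale.
    """

    def __init__(self, base_width: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = base_width
        self.base_width = c
        self.enc1 = _ConvBlock(3, c, rng)
        self.pool1 = MaxPool2()
        self.enc2 = _ConvBlock(c, 2 * c, rng)
        self.pool2 = MaxPool2()
        self.bott = _ConvBlock(2 * c, 4 * c, rng, double=True)
        self.up2 = Upsample2()
        self.dec2 = _ConvBlock(4 * c + 2 * c, 2 * c, rng)
        self.up1 = Upsample2()
        self.dec1 = _ConvBlock(2 * c + c, c, rng)
        self.head = Conv2D(c, N_CLASSES, 3, rng)

    # -- parameter groups --------------------------------------------------

    def encoder_params(self) -> list[Param]:
        return self.enc1.params() + self.enc2.params() + self.bott.params()

    def decoder_params(self) -> list[Param]:
        return self.dec2.params() + self.dec1.params() + self.head.params()

    def params(self) -> list[Param]:
        return self.encoder_params() + self.decoder_params()

    def set_encoder_trainable(self, trainable: bool) -> None:
        for p in self.encoder_params():
            p.trainable = trainable

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- passes ------------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 3, H, W) float32 -> (N, n_classes, H, W) logits."""
        s1 = self.enc1.forward(x)
        s2 = self.enc2.forward(self.pool1.forward(s1))
        b = self.bott.forward(self.pool2.forward(s2))
        u2 = np.concatenate([self.up2.forward(b), s2], axis=1)
        d2 = self.dec2.forward(u2)
        u1 = np.concatenate([self.up1.forward(d2), s1], axis=1)
        d1 = self.dec1.forward(u1)
        self._split2 = b.shape[1]
        self._split1 = d2.shape[1]
        return self.head.forward(d1)

    def backward(self, dlogits: np.ndarray) -> None:
        dd1 = self.head.backward(dlogits)
        du1 = self.dec1.backward(dd1)
        dd2, ds1_skip = du1[:, : self._split1], du1[:, self._split1 :]
        du2 = self.dec2.backward(self.up1.backward(dd2))
        db, ds2_skip = du2[:, : self._split2], du2[:, self._split2 :]
        ds2 = self.pool2.backward(self.bott.backward(self.up2.backward(db)))
        ds1 = self.pool1.backward(
            self.enc2.backward(ds2 + ds2_skip)
        )
        self.enc1.backward(ds1 + ds1_skip)

    def predict_logits(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i : i + batch_size]))
        return np.concatenate(out, axis=0)

    def predict_labels(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        return self.predict_logits(x, batch_size).argmax(axis=1).astype(np.uint8)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        state = {
            "base_width": self.base_width,
            "weights": [p.value for p in self.params()],
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(base_width=state["base_width"])
        for p, w in zip(model.params(), state["weights"]):
            p.value = np.asarray(w, dtype=np.float32)
            p.grad = np.zeros_like(p.value)
        return model


def build_model(backbone: str = "unet16", seed: int = 0) -> UNet:
    """Construct a model from a backbone identifier."""
    if backbone not in _BACKBONES:
        raise ValueError(
            f"unknown backbone {backbone!r}; available: {sorted(_BACKBONES)}"
        )
    return UNet(base_width=_BACKBONES[backbone], seed=seed)
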