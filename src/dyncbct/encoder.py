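"""Convolutional motion encoder: projection image -> 9 MBC coefficients.

Six 3x3 convolution layers (channels 2, 4, 8, 16, 32, 32; stride 2, padding
1), each followed by batch normalization and ReLU, then a single linear head
with nine outputs — one coefficient per motion-basis component.  Inputs are
detector images resampled to 128x96 by area averaging and standardized to
zero mean / unit variance per frame, so the coefficients are driven by image
content rather than exposure scale.

Forward and backward passes are written directly on numpy (im2col); batch
normalization uses batch statistics during training and running averages in
inference mode, so encoding is deterministic at evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MotionEncoderSpec", "MotionEncoder", "prepare_input"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class MotionEncoderSpec:
    input_hw: tuple[int, int] = (96, 128)  # (v rows, u columns)
    channels: tuple[int, ...] = (2, 4, 8, 16, 32, 32)
    n_out: int = 9
    kernel: int = 3
    stride: int = 2


def prepare_input(frame: np.ndarray, spec: MotionEncoderSpec) -> np.ndarray:
    """Area-average a detector frame to the encoder size and standardize it."""
    if not np.all(np.isfinite(frame)):
        raise ValueError("encoder input must be finite")
    h, w = spec.input_hw
    fh, fw = frame.shape
    if (fh, fw) != (h, w):
        if fh % h == 0 and fw % w == 0:
            frame = frame.reshape(h, fh // h, w, fw // w).mean(axis=(1, 3))
        else:
            from skimage.transform import resize

            frame = resize(frame, (h, w), order=1, anti_aliasing=True, mode="edge")
    mu = frame.mean()
    sd = frame.std()
    return (frame - mu) / (sd if sd > 1e-12 else 1.0)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, k, k, ho, wo),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        writeable=False,
    )
    return cols.reshape(b, c * k * k, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int, ho: int, wo: int):
    b, c, h, w = x_shape
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(b, c, k, k, ho, wo)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki : ki + ho * stride : stride, kj : kj + wo * stride : stride] += cols[
                :, :, ki, kj
            ]
    return xp[:, :, pad : pad + h, pad : pad + w]


class MotionEncoder:
    """Parameter container + forward/backward for the coefficient network."""

    def __init__(self, spec: MotionEncoderSpec | None = None, seed: int = 0):
        self.spec = spec or MotionEncoderSpec()
        rng = np.random.default_rng(seed)
        s = self.spec
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        c_in = 1
        h, w = s.input_hw
        for i, c_out in enumerate(s.channels):
            fan_in = c_in * s.kernel * s.kernel
            self.params[f"conv{i}_w"] = rng.standard_normal(
                (c_out, c_in, s.kernel, s.kernel)
            ) * np.sqrt(2.0 / fan_in)
            self.params[f"conv{i}_b"] = np.zeros(c_out)
            self.params[f"bn{i}_g"] = np.ones(c_out)
            self.params[f"bn{i}_b"] = np.zeros(c_out)
            self.running[f"bn{i}_mean"] = np.zeros(c_out)
            self.running[f"bn{i}_var"] = np.ones(c_out)
            c_in = c_out
            h = (h + 2 - s.kernel) // s.stride + 1
            w = (w + 2 - s.kernel) // s.stride + 1
        self.n_features = c_in * h * w
        self.params["fc_w"] = rng.standard_normal((s.n_out, self.n_features)) * np.sqrt(
            1.0 / self.n_features
        )
        self.params["fc_b"] = np.zeros(s.n_out)

    def forward(self, x: np.ndarray, training: bool = False):
        """x: (B, H, W) standardized frames -> (B, 9) coefficients + cache."""
        s = self.spec
        x = x[:, None].astype(np.float64)
        cache: dict = {"training": training, "layers": []}
        for i in range(len(s.channels)):
            w = self.params[f"conv{i}_w"]
            b = self.params[f"conv{i}_b"]
            c_out = w.shape[0]
            cols, ho, wo = _im2col(x, s.kernel, s.stride, 1)
            pre = np.einsum("oc,bcp->bop", w.reshape(c_out, -1), cols) + b[None, :, None]
            pre = pre.reshape(x.shape[0], c_out, ho, wo)
            if training:
                mean = pre.mean(axis=(0, 2, 3))
                var = pre.var(axis=(0, 2, 3))
                self.running[f"bn{i}_mean"] *= 1 - _BN_MOMENTUM
                self.running[f"bn{i}_mean"] += _BN_MOMENTUM * mean
                self.running[f"bn{i}_var"] *= 1 - _BN_MOMENTUM
                self.running[f"bn{i}_var"] += _BN_MOMENTUM * var
            else:
                mean = self.running[f"bn{i}_mean"]
                var = self.running[f"bn{i}_var"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xn = (pre - mean[None, :, None, None]) * inv_std[None, :, None, None]
            act = self.params[f"bn{i}_g"][None, :, None, None] * xn + self.params[
                f"bn{i}_b"
            ][None, :, None, None]
            out = np.maximum(act, 0.0)
            cache["layers"].append(
                {"x_shape": x.shape, "cols": cols, "ho": ho, "wo": wo,
                 "xn": xn, "inv_std": inv_std, "relu_mask": act > 0}
            )
            x = out
        feat = x.reshape(x.shape[0], -1)
        cache["feat"] = feat
        w_out = feat @ self.params["fc_w"].T + self.params["fc_b"]
        if not np.all(np.isfinite(w_out)):
            raise FloatingPointError("encoder produced non-finite coefficients")
        return w_out, cache

    def encode(self, frame: np.ndarray) -> np.ndarray:
        """Deterministic inference for a single detector frame."""
        x = prepare_input(np.asarray(frame, dtype=np.float64), self.spec)
        w, _ = self.forward(x[None], training=False)
        return w[0]

    def backward(self, cache: dict, grad_out: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of sum(grad_out * output) w.r.t. every parameter."""
        s = self.spec
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        feat = cache["feat"]
        grads["fc_w"] = grad_out.T @ feat
        grads["fc_b"] = grad_out.sum(axis=0)
        gx = (grad_out @ self.params["fc_w"]).reshape(
            feat.shape[0], -1
        )
        last = cache["layers"][-1]
        b = feat.shape[0]
        c_last = self.params[f"conv{len(s.channels)-1}_w"].shape[0]
        gx = gx.reshape(b, c_last, last["ho"], last["wo"])
        for i in reversed(range(len(s.channels))):
            lay = cache["layers"][i]
            gx = gx * lay["relu_mask"]
            xn = lay["xn"]
            grads[f"bn{i}_g"] = (gx * xn).sum(axis=(0, 2, 3))
            grads[f"bn{i}_b"] = gx.sum(axis=(0, 2, 3))
            g = self.params[f"bn{i}_g"]
            gxn = gx * g[None, :, None, None]
            if cache["training"]:
                n = gx.shape[0] * gx.shape[2] * gx.shape[3]
                inv_std = lay["inv_std"][None, :, None, None]
                gpre = (
                    gxn
                    - gxn.mean(axis=(0, 2, 3), keepdims=True)
                    - xn * (gxn * xn).mean(axis=(0, 2, 3), keepdims=True)
                ) * inv_std
            else:
                gpre = gxn * lay["inv_std"][None, :, None, None]
            c_out = gpre.shape[1]
            gpre_f = gpre.reshape(b, c_out, -1)
            w = self.params[f"conv{i}_w"]
            grads[f"conv{i}_w"] = np.einsum("bop,bcp->oc", gpre_f, lay["cols"]).reshape(
                w.shape
            )
            grads[f"conv{i}_b"] = gpre_f.sum(axis=(0, 2))
            gcols = np.einsum("oc,bop->bcp", w.reshape(c_out, -1), gpre_f)
            gx = _col2im(gcols, lay["x_shape"], s.kernel, s.stride, 1, lay["ho"], lay["wo"])
        return grads
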