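"""A compact, fully seeded numpy CNN with depth-wise separable convolutions.

The prognostic encoder maps an RGB patch to a dense feature vector through a
MobileNet-style stack: an input average-pool (cheap downsampling), a small
standard convolution stem, then depth-wise separable blocks (depth-wise 3x3
followed by a pointwise 1x1 mix), global average pooling, and a linear Cox
head producing a scalar per-patch risk contribution.  Forward and backward
passes are analytic; parameters are updated with Adam.  Everything is plain
numpy so training is single-process and exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EncoderConfig", "SepConvEncoder", "Adam"]


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """View of sliding k x k windows of a padded NHWC array (no copy)."""
    n, h, w, c = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    return np.lib.stride_tricks.as_strided(
        x, (n, oh, ow, k, k, c), (s0, s1 * stride, s2 * stride, s1, s2, s3)
    )


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int) -> np.ndarray:
    """Scatter-add adjoint of :func:`_im2col`."""
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    _, oh, ow = dcols.shape[:3]
    for i in range(k):
        for j in range(k):
            dx[:, i : i + oh * stride : stride, j : j + ow * stride : stride, :] += dcols[
                :, :, :, i, j, :
            ]
    return dx


def _pad_same(x: np.ndarray, k: int) -> tuple:
    p = k // 2
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))), p


@dataclass
class EncoderConfig:
    patch_edge: int = 64
    in_channels: int = 3
    input_pool: int = 4  # average-pool factor applied to the raw patch
    stem_channels: int = 8
    stem_stride: int = 2
    blocks: tuple = ((16, 2),)  # (out_channels, stride) per separable block

    @property
    def feature_dim(self) -> int:
        return self.blocks[-1][0] if self.blocks else self.stem_channels


class SepConvEncoder:
    """Patch encoder + linear Cox head.  Parameters live in ``self.params``."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        c_in = config.in_channels
        k = 3

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float64)

        self.params["stem_w"] = he((k, k, c_in, config.stem_channels), k * k * c_in)
        self.params["stem_b"] = np.zeros(config.stem_channels)
        c = config.stem_channels
        for bi, (c_out, _) in enumerate(config.blocks):
            self.params[f"dw{bi}_w"] = he((k, k, c), k * k)
            self.params[f"dw{bi}_b"] = np.zeros(c)
            self.params[f"pw{bi}_w"] = he((c, c_out), c)
            self.params[f"pw{bi}_b"] = np.zeros(c_out)
            c = c_out
        self.params["head_w"] = he((c,), c)
        self.params["head_b"] = np.zeros(1)

    # -- forward -----------------------------------------------------------

    def features(self, x: np.ndarray, want_cache: bool = False):
        """Encode patches (N, E, E, 3 float in ~[-1, 1]) to (N, F) features."""
        cfg = self.config
        cache = {"acts": []}
        p = cfg.input_pool
        if p > 1:
            n, h, w, c = x.shape
            x = x.reshape(n, h // p, p, w // p, p, c).mean(axis=(2, 4))
        cache["pooled_shape"] = x.shape

        xp, _ = _pad_same(x, 3)
        cols = _im2col(xp, 3, cfg.stem_stride)
        z = np.tensordot(cols, self.params["stem_w"], axes=3) + self.params["stem_b"]
        a = np.maximum(z, 0.0)
        cache["acts"].append(("stem", xp.shape, cols if want_cache else None, z > 0))
        x = a

        for bi, (c_out, stride) in enumerate(cfg.blocks):
            xp, _ = _pad_same(x, 3)
            cols = _im2col(xp, 3, stride)
            zd = np.einsum("nijklc,klc->nijc", cols, self.params[f"dw{bi}_w"]) + self.params[
                f"dw{bi}_b"
            ]
            ad = np.maximum(zd, 0.0)
            zp = ad @ self.params[f"pw{bi}_w"] + self.params[f"pw{bi}_b"]
            ap = np.maximum(zp, 0.0)
            cache["acts"].append(
                ("block", bi, stride, xp.shape, cols if want_cache else None, zd > 0, ad, zp > 0)
            )
            x = ap

        cache["pre_gap_shape"] = x.shape
        feats = x.mean(axis=(1, 2))
        if want_cache:
            return feats, cache
        return feats

    def head(self, feats: np.ndarray) -> np.ndarray:
        return feats @ self.params["head_w"] + self.params["head_b"][0]

    def patch_scores(self, x: np.ndarray) -> np.ndarray:
        """Per-patch scalar risk contributions (head applied to each feature)."""
        return self.head(self.features(x))

    # -- backward ----------------------------------------------------------

    def backward(self, dscores: np.ndarray, feats: np.ndarray, cache: dict) -> dict:
        """Gradients of sum(dscores * patch_scores) w.r.t. all parameters."""
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["head_w"] = feats.T @ dscores
        grads["head_b"] = np.array([dscores.sum()])
        dfeat = np.outer(dscores, self.params["head_w"])

        n, oh, ow, c = cache["pre_gap_shape"]
        dx = np.broadcast_to(dfeat[:, None, None, :] / (oh * ow), (n, oh, ow, c)).copy()

        for entry in reversed(cache["acts"]):
            if entry[0] == "block":
                _, bi, stride, xp_shape, cols, dmask, ad, pmask = entry
                dzp = dx * pmask
                grads[f"pw{bi}_w"] = np.tensordot(ad, dzp, axes=([0, 1, 2], [0, 1, 2]))
                grads[f"pw{bi}_b"] = dzp.sum(axis=(0, 1, 2))
                dad = dzp @ self.params[f"pw{bi}_w"].T
                dzd = dad * dmask
                grads[f"dw{bi}_w"] = np.einsum("nijklc,nijc->klc", cols, dzd)
                grads[f"dw{bi}_b"] = dzd.sum(axis=(0, 1, 2))
                dcols = dzd[:, :, :, None, None, :] * self.params[f"dw{bi}_w"][None, None, None]
                dxp = _col2im(dcols, xp_shape, 3, stride)
                dx = dxp[:, 1:-1, 1:-1, :]
            else:
                _, xp_shape, cols, mask = entry
                dz = dx * mask
                grads["stem_w"] = np.tensordot(cols, dz, axes=([0, 1, 2], [0, 1, 2]))
                grads["stem_b"] = dz.sum(axis=(0, 1, 2))
                # input gradient not needed
        return grads

    # -- parameter plumbing -------------------------------------------------

    def get_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()

    def save(self, path) -> None:
        np.savez(path, **self.params, _patch_edge=self.config.patch_edge,
                 _input_pool=self.config.input_pool, _stem=self.config.stem_channels,
                 _stem_stride=self.config.stem_stride,
                 _blocks=np.asarray(self.config.blocks))

    @classmethod
    def load(cls, path) -> "SepConvEncoder":
        data = np.load(path)
        cfg = EncoderConfig(
            patch_edge=int(data["_patch_edge"]),
            input_pool=int(data["_input_pool"]),
            stem_channels=int(data["_stem"]),
            stem_stride=int(data["_stem_stride"]),
            blocks=tuple((int(a), int(b)) for a, b in data["_blocks"]),
        )
        enc = cls(cfg, np.random.default_rng(0))
        for k in enc.params:
            enc.params[k] = data[k]
        return enc


@dataclass
class Adam:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict, grads: dict) -> None:
        self._t += 1
        for k, g in grads.items():
            if k not in self._m:
                self._m[k] = np.zeros_like(g)
                self._v[k] = np.zeros_like(g)
            self._m[k] = self.beta1 * self._m[k] + (1 - self.beta1) * g
            self._v[k] = self.beta2 * self._v[k] + (1 - self.beta2) * g * g
            mhat = self._m[k] / (1 - self.beta1**self._t)
            vhat = self._v[k] / (1 - self.beta2**self._t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
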