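"""Layers with explicit forward/backward passes on ``(C, X, Y, Z)`` tensors."""

from __future__ import annotations

import numpy as np

# Compute dtype for the whole substrate; float64 is used by the gradient-check
# tests, float32 everywhere else.
DTYPE = np.float32


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, kernel 3x3x3 or 1x1x1, stride 1, zero padding ("same").

    He-normal initialization; the fan-in uses the full kernel support.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, rng=None, bias=True):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        std = float(np.sqrt(2.0 / fan_in))
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel, kernel)))
        self.b = Param(np.zeros(c_out)) if bias else None
        self._x = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x):
        self._x = x
        C, X, Y, Z = x.shape
        if self.kernel == 1:
            out = (self.w.value[:, :, 0, 0, 0] @ x.reshape(C, -1)).reshape(
                self.c_out, X, Y, Z
            )
        else:
            xp = np.zeros((C, X + 2, Y + 2, Z + 2), dtype=DTYPE)
            xp[:, 1:-1, 1:-1, 1:-1] = x
            self._xp = xp
            out = np.zeros((self.c_out, X * Y * Z), dtype=DTYPE)
            w = self.w.value
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        xs = np.ascontiguousarray(
                            xp[:, i : i + X, j : j + Y, k : k + Z]
                        ).reshape(C, -1)
                        out += w[:, :, i, j, k] @ xs
            out = out.reshape(self.c_out, X, Y, Z)
        if self.b is not None:
            out += self.b.value[:, None, None, None]
        return out

    def backward(self, g):
        x = self._x
        C, X, Y, Z = x.shape
        gf = g.reshape(self.c_out, -1)
        if self.b is not None:
            self.b.grad += gf.sum(axis=1)
        if self.kernel == 1:
            self.w.grad[:, :, 0, 0, 0] += gf @ x.reshape(C, -1).T
            return (self.w.value[:, :, 0, 0, 0].T @ gf).reshape(C, X, Y, Z)
        w = self.w.value
        gxp = np.zeros((C, X + 2, Y + 2, Z + 2), dtype=DTYPE)
        gfc = np.ascontiguousarray(gf)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = np.ascontiguousarray(
                        self._xp[:, i : i + X, j : j + Y, k : k + Z]
                    ).reshape(C, -1)
                    self.w.grad[:, :, i, j, k] += gfc @ xs.T
                    gxp[:, i : i + X, j : j + Y, k : k + Z] += (
                        w[:, :, i, j, k].T @ gfc
                    ).reshape(C, X, Y, Z)
        self._xp = None
        return np.ascontiguousarray(gxp[:, 1:-1, 1:-1, 1:-1])


class InstanceNorm3d(Layer):
    """Per-channel normalization over the spatial axes of one instance, with
    a learned affine (gamma, beta)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        C = x.shape[0]
        flat = x.reshape(C, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mu) * inv
        self._xhat, self._inv, self._shape = xhat, inv, x.shape
        out = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        return out.reshape(x.shape).astype(DTYPE)

    def backward(self, g):
        C = g.shape[0]
        gf = g.reshape(C, -1)
        xhat, inv = self._xhat, self._inv
        n = gf.shape[1]
        self.gamma.grad += (gf * xhat).sum(axis=1)
        self.beta.grad += gf.sum(axis=1)
        gxhat = gf * self.gamma.value[:, None]
        gx = inv / n * (
            n * gxhat
            - gxhat.sum(axis=1, keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=1, keepdims=True)
        )
        return gx.reshape(self._shape).astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x):
        self._neg = x < 0
        out = x.copy()
        out[self._neg] *= self.slope
        return out

    def backward(self, g):
        out = g.copy()
        out[self._neg] *= self.slope
        return out


def _blocks(x):
    """(C, X, Y, Z) -> (C, X/2, Y/2, Z/2, 8) view-reshape of 2x2x2 blocks."""
    C, X, Y, Z = x.shape
    b = x.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2)
    return np.moveaxis(b, (2, 4, 6), (4, 5, 6)).reshape(C, X // 2, Y // 2, Z // 2, 8)


def _unblocks(b, shape):
    C, X, Y, Z = shape
    b = b.reshape(C, X // 2, Y // 2, Z // 2, 2, 2, 2)
    return np.moveaxis(b, (4, 5, 6), (2, 4, 6)).reshape(C, X, Y, Z)


class AvgPool3d(Layer):
    """2x2x2 average pooling (even input edges required)."""

    def forward(self, x):
        self._shape = x.shape
        return _blocks(x).mean(axis=-1)

    def backward(self, g):
        b = np.repeat(g[..., None] / 8.0, 8, axis=-1)
        return _unblocks(b, self._shape).astype(DTYPE)


class MaxPool3d(Layer):
    """2x2x2 max pooling; ties route the gradient to the first maximum."""

    def forward(self, x):
        self._shape = x.shape
        b = _blocks(x)
        self._arg = b.argmax(axis=-1)
        return b.max(axis=-1)

    def backward(self, g):
        b = np.zeros(self._arg.shape + (8,), dtype=DTYPE)
        np.put_along_axis(b, self._arg[..., None], g[..., None], axis=-1)
        return _unblocks(b, self._shape)


def _upsample_axis(x, axis):
    """Double one axis with linear interpolation (half-voxel aligned grids).

    Output sample 2j sits a quarter voxel left of input sample j and 2j+1 a
    quarter voxel right, giving weights (0.25, 0.75) / (0.75, 0.25) with edge
    clamping -- the usual align_corners=False convention.
    """
    x = np.moveaxis(x, axis, -1)
    left = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    right = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    even = 0.75 * x + 0.25 * left
    odd = 0.75 * x + 0.25 * right
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=DTYPE)
    out[..., 0::2] = even
    out[..., 1::2] = odd
    return np.moveaxis(out, -1, axis)


def _upsample_axis_adjoint(g, axis):
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    gx = 0.75 * (ge + go)
    # even output 2(j+1) takes 0.25 from x[j] via its left neighbour
    gx[..., :-1] += 0.25 * ge[..., 1:]
    gx[..., 0] += 0.25 * ge[..., 0]  # clamped edge
    # odd output 2(j-1)+1 takes 0.25 from x[j] via its right neighbour
    gx[..., 1:] += 0.25 * go[..., :-1]
    gx[..., -1] += 0.25 * go[..., -1]  # clamped edge
    return np.moveaxis(gx.astype(DTYPE), -1, axis)


class TrilinearUpsample(Layer):
    """Factor-2 trilinear upsampling (separable along the three axes)."""

    def forward(self, x):
        for axis in (1, 2, 3):
            x = _upsample_axis(x, axis)
        return x

    def backward(self, g):
        for axis in (3, 2, 1):
            g = _upsample_axis_adjoint(g, axis)
        return g
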