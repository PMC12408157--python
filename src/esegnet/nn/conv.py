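"""N-dimensional convolution (2 or 3 spatial axes) with groups, stride,
dilation and zero "same" padding.

Two execution paths produce identical results (up to float rounding):

* a generic kernel-tap loop (any stride/groups), used for small kernels;
* an FFT path for stride-1 depthwise convolutions with large kernels,
  where looping over k^d taps would dominate the run time.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.signal import fftconvolve

from .core import Module, Parameter

__all__ = ["Conv"]

# taps above this count trigger the FFT path (depthwise, stride 1 only)
_FFT_TAP_THRESHOLD = 32


def _tuplize(v, dim):
    if np.isscalar(v):
        return (int(v),) * dim
    t = tuple(int(x) for x in v)
    if len(t) != dim:
        raise ValueError(f"expected {dim} entries, got {v!r}")
    return t


class Conv(Module):
    """Bias-free by default; ``padding=None`` means symmetric "same"
    padding ``((k-1)*dilation)//2`` per axis (odd kernels only)."""

    def __init__(self, dim, in_channels, out_channels, kernel, *, stride=1,
                 dilation=1, groups=1, padding=None, bias=False, rng=None,
                 dtype=np.float32):
        super().__init__()
        if dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        self.dim = dim
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel = _tuplize(kernel, dim)
        self.stride = _tuplize(stride, dim)
        self.dilation = _tuplize(dilation, dim)
        self.groups = int(groups)
        if padding is None and any(k % 2 == 0 for k in self.kernel):
            raise ValueError("even kernels require explicit padding")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError("channels must be divisible by groups")
        if padding is None:
            padding = tuple(((k - 1) * d) // 2
                            for k, d in zip(self.kernel, self.dilation))
        self.padding = _tuplize(padding, dim)

        rng = rng if rng is not None else np.random.default_rng()
        cin_g = self.in_channels // self.groups
        fan_out = self.out_channels // self.groups * int(np.prod(self.kernel))
        std = np.sqrt(2.0 / fan_out)
        self.weight = Parameter(
            (rng.standard_normal((self.out_channels, cin_g) + self.kernel) * std)
            .astype(dtype))
        self.bias = Parameter(np.zeros(self.out_channels, dtype)) if bias else None

        self._sp = "xyz"[: dim]
        self._depthwise = (self.groups == self.in_channels == self.out_channels)
        self._use_fft = (self._depthwise
                         and all(s == 1 for s in self.stride)
                         and int(np.prod(self.kernel)) > _FFT_TAP_THRESHOLD)

    # -- helpers -----------------------------------------------------------
    def out_shape(self, spatial):
        eff = tuple((k - 1) * d + 1 for k, d in zip(self.kernel, self.dilation))
        return tuple((s + 2 * p - e) // st + 1
                     for s, p, e, st in zip(spatial, self.padding, eff, self.stride))

    def _pad(self, x):
        pads = [(0, 0), (0, 0)] + [(p, p) for p in self.padding]
        if all(p == 0 for p in self.padding):
            return x
        return np.pad(x, pads)

    def _tap_slices(self, tap, out_spatial):
        return tuple(slice(t * d, t * d + (o - 1) * s + 1, s)
                     for t, d, s, o in zip(tap, self.dilation, self.stride, out_spatial))

    def _dense_kernel(self):
        """Kernel with dilation written out as zeros; shape (C, eff...)."""
        eff = tuple((k - 1) * d + 1 for k, d in zip(self.kernel, self.dilation))
        dense = np.zeros((self.out_channels,) + eff, self.weight.data.dtype)
        idx = (slice(None),) + tuple(slice(None, None, d) for d in self.dilation)
        dense[idx] = self.weight.data[:, 0]
        return dense

    # -- forward -----------------------------------------------------------
    def forward(self, x):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        if x.ndim != 2 + self.dim:
            raise ValueError(f"expected {2 + self.dim}D input, got shape {x.shape}")
        self._in_spatial = x.shape[2:]
        if self._use_fft:
            y = self._forward_fft(x)
        else:
            y = self._forward_taps(x)
        if self.bias is not None:
            y += self.bias.data.reshape((1, -1) + (1,) * self.dim)
        return y

    def _forward_taps(self, x):
        xp = self._pad(x)
        self._xp = xp
        n = x.shape[0]
        g = self.groups
        out_spatial = self.out_shape(x.shape[2:])
        xg = xp.reshape((n, g, self.in_channels // g) + xp.shape[2:])
        w = self.weight.data.reshape(
            (g, self.out_channels // g, self.in_channels // g) + self.kernel)
        y = np.zeros((n, g, self.out_channels // g) + out_spatial, x.dtype)
        for tap in itertools.product(*[range(k) for k in self.kernel]):
            sl = (slice(None),) * 3 + self._tap_slices(tap, out_spatial)
            y += np.einsum(f"ngc{self._sp},goc->ngo{self._sp}", xg[sl],
                           w[(slice(None),) * 3 + tap])
        return y.reshape((n, self.out_channels) + out_spatial)

    def _forward_fft(self, x):
        self._x = x
        dense = self._dense_kernel()
        axes = tuple(range(2, 2 + self.dim))
        flip = tuple(slice(None, None, -1) for _ in range(self.dim))
        y = fftconvolve(x, dense[None][(slice(None), slice(None)) + flip],
                        mode="same", axes=axes)
        return y.astype(x.dtype, copy=False)

    # -- backward ----------------------------------------------------------
    def backward(self, gy):
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0,) + tuple(range(2, 2 + self.dim)))
        if self._use_fft:
            return self._backward_fft(gy)
        return self._backward_taps(gy)

    def _backward_taps(self, gy):
        n = gy.shape[0]
        g = self.groups
        out_spatial = gy.shape[2:]
        gyg = gy.reshape((n, g, self.out_channels // g) + out_spatial)
        xg = self._xp.reshape((n, g, self.in_channels // g) + self._xp.shape[2:])
        w = self.weight.data.reshape(
            (g, self.out_channels // g, self.in_channels // g) + self.kernel)
        gw = np.zeros_like(w)
        gxp = np.zeros_like(xg)
        for tap in itertools.product(*[range(k) for k in self.kernel]):
            sl = (slice(None),) * 3 + self._tap_slices(tap, out_spatial)
            tapidx = (slice(None),) * 3 + tap
            gw[tapidx] += np.einsum(f"ngo{self._sp},ngc{self._sp}->goc",
                                    gyg, xg[sl])
            gxp[sl] += np.einsum(f"ngo{self._sp},goc->ngc{self._sp}",
                                 gyg, w[tapidx])
        self.weight.grad += gw.reshape(self.weight.data.shape)
        gxp = gxp.reshape((n, self.in_channels) + self._xp.shape[2:])
        if all(p == 0 for p in self.padding):
            return gxp
        unpad = (slice(None), slice(None)) + tuple(
            slice(p, p + s) for p, s in zip(self.padding, self._in_spatial))
        return gxp[unpad]

    def _backward_fft(self, gy):
        x = self._x
        axes = tuple(range(2, 2 + self.dim))
        dense = self._dense_kernel()
        gx = fftconvolve(gy, dense[None], mode="same", axes=axes)
        # dw[c, t] = sum_p x[c, p + offset(t)] * gy[c, p]: correlation of x
        # with gy, read off at the kernel tap offsets around the center.
        flip = (slice(None), slice(None)) + tuple(
            slice(None, None, -1) for _ in range(self.dim))
        full = fftconvolve(x, gy[flip], mode="full", axes=axes).sum(axis=0)
        centers = [s - 1 for s in x.shape[2:]]
        eff = tuple((k - 1) * d + 1 for k, d in zip(self.kernel, self.dilation))
        sl = (slice(None),) + tuple(
            slice(c - (e - 1) // 2, c - (e - 1) // 2 + e)
            for c, e in zip(centers, eff))
        corr = full[sl]
        taps = (slice(None),) + tuple(slice(None, None, d) for d in self.dilation)
        self.weight.grad += corr[taps][:, None].astype(
            self.weight.grad.dtype, copy=False)
        return gx.astype(gy.dtype, copy=False)
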