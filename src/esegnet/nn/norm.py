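"""Batch normalization over (batch, spatial) per channel, 2D or 3D."""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter

__all__ = ["BatchNorm"]


class BatchNorm(Module):
    """Standard running-statistics batch norm.

    Training uses batch statistics (biased variance for normalization,
    unbiased for the running update); inference uses the running ones.
    """

    def __init__(self, channels, *, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.channels = int(channels)
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.gamma = Parameter(np.ones(channels, dtype))
        self.beta = Parameter(np.zeros(channels, dtype))
        self.register_buffer("running_mean", np.zeros(channels, dtype))
        self.register_buffer("running_var", np.ones(channels, dtype))

    def _shape(self, ndim):
        return (1, self.channels) + (1,) * (ndim - 2)

    def forward(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        axes = (0,) + tuple(range(2, x.ndim))
        shp = self._shape(x.ndim)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.size // self.channels
            corr = m / max(m - 1, 1)
            self._set_buffer("running_mean",
                             ((1 - self.momentum) * self.running_mean
                              + self.momentum * mean).astype(x.dtype))
            self._set_buffer("running_var",
                             ((1 - self.momentum) * self.running_var
                              + self.momentum * var * corr).astype(x.dtype))
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) / std.reshape(shp)
        self._xhat, self._std, self._axes = xhat, std, axes
        return self.gamma.data.reshape(shp) * xhat + self.beta.data.reshape(shp)

    def backward(self, gy):
        shp = self._shape(gy.ndim)
        axes = self._axes
        xhat, std = self._xhat, self._std
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        gs = self.gamma.data.reshape(shp) / std.reshape(shp)
        if not self.training:
            return gy * gs
        m = gy.size // self.channels
        gmean = gy.mean(axis=axes).reshape(shp)
        gdot = (gy * xhat).mean(axis=axes).reshape(shp)
        return gs * (gy - gmean - xhat * gdot)
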