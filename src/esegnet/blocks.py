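"""Convolutional building blocks.

``GConv`` is the depthwise-separable unit (pointwise conv -> depthwise
conv(k) -> batch norm -> ReLU); ``DConv`` is its dilated variant with the
kernel fixed at 3.  ``MLKConv`` stacks two four-branch multi-scale stages of
these units with residual channel mixing.  ``UpConv`` compresses a stage and
resizes it to full resolution.  ``DoubleConv`` and ``SEBasicConv`` are the
alternative refinement heads; all blocks exist in 2D and 3D form.

All pointwise/depthwise convolutions are bias-free; batch norm contributes
``2*C_out`` learnable entries, which makes the closed-form parameter counts
in :func:`count_params` exact.
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm, Conv, Identity, Module, ModuleList, ReLU
from .types import BlockSpec

__all__ = [
    "GConv", "DConv", "MLKConv", "UpConv", "DoubleConv", "SEBasicConv",
    "make_refinement", "count_params", "instantiate",
    "MLK_KERNELS", "MLK_DILATIONS",
]

MLK_KERNELS = (3, 5, 7, 11)
MLK_DILATIONS = (3, 5, 7, 11)


class GConv(Module):
    """Pointwise conv -> depthwise conv(k, dilation) -> BN -> ReLU.

    ``relu=False`` drops the trailing rectifier (used by the final channel
    mixer inside :class:`MLKConv`, which feeds a residual sum and should not
    clip negative corrections).
    """

    def __init__(self, dim, in_channels, out_channels, kernel, *, dilation=1,
                 relu=True, rng=None, dtype=np.float32):
        super().__init__()
        self.pw = Conv(dim, in_channels, out_channels, 1, rng=rng, dtype=dtype)
        self.dw = Conv(dim, out_channels, out_channels, kernel,
                       dilation=dilation, groups=out_channels, rng=rng,
                       dtype=dtype)
        self.bn = BatchNorm(out_channels, dtype=dtype)
        self.relu = ReLU() if relu else Identity()
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x):
        return self.relu(self.bn(self.dw(self.pw(x))))

    def backward(self, gy):
        return self.pw.backward(self.dw.backward(self.bn.backward(
            self.relu.backward(gy))))


class DConv(GConv):
    """GConv with kernel fixed at 3 and a configurable dilation rate; its
    effective depthwise receptive field is ``2*r + 1`` per axis while the
    parameter count is independent of ``r``."""

    def __init__(self, dim, in_channels, out_channels, dilation, *, relu=True,
                 rng=None, dtype=np.float32):
        super().__init__(dim, in_channels, out_channels, 3, dilation=dilation,
                         relu=relu, rng=rng, dtype=dtype)


class MLKConv(Module):
    """Multi-scale large-kernel refinement block.

    Stage 1: four parallel GConv branches (kernels 3/5/7/11), each C -> C/4,
    concatenated back to C, mixed by a kernel-1 GConv and added residually.
    Stage 2: the same pattern with kernel-3 DConv branches at dilations
    3/5/7/11; the final kernel-1 mixer omits its ReLU.  Channels and spatial
    shape are preserved; C must be divisible by 4.
    """

    def __init__(self, dim, channels, *, rng=None, dtype=np.float32):
        super().__init__()
        if channels % 4:
            raise ValueError(
                f"MLKConv requires channels divisible by 4, got {channels}")
        c4 = channels // 4
        self.channels = channels
        self.branches1 = ModuleList(
            [GConv(dim, channels, c4, k, rng=rng, dtype=dtype)
             for k in MLK_KERNELS])
        self.mix1 = GConv(dim, channels, channels, 1, rng=rng, dtype=dtype)
        self.branches2 = ModuleList(
            [DConv(dim, channels, c4, r, rng=rng, dtype=dtype)
             for r in MLK_DILATIONS])
        self.mix2 = GConv(dim, channels, channels, 1, relu=False, rng=rng,
                          dtype=dtype)

    def forward(self, f):
        if f.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {f.shape[1]}")
        f1 = np.concatenate([b(f) for b in self.branches1], axis=1)
        f2 = f + self.mix1(f1)
        f3 = np.concatenate([b(f2) for b in self.branches2], axis=1)
        return f2 + self.mix2(f3)

    def backward(self, gy):
        c4 = self.channels // 4
        g_f2 = gy.copy()
        g_f3 = self.mix2.backward(gy)
        for i, b in enumerate(self.branches2):
            g_f2 += b.backward(g_f3[:, i * c4:(i + 1) * c4])
        g_f = g_f2.copy()
        g_f1 = self.mix1.backward(g_f2)
        for i, b in enumerate(self.branches1):
            g_f += b.backward(g_f1[:, i * c4:(i + 1) * c4])
        return g_f


class UpConv(Module):
    """Kernel-3 compression conv -> ReLU -> BN (in that order) followed by
    nearest-neighbor resize to a target resolution.

    ``order="conv_bn_relu"`` switches to the conventional ordering for
    ablation.  The resize only upsamples; a target smaller than the source
    is rejected.
    """

    def __init__(self, dim, in_channels, width, *, order="conv_relu_bn",
                 rng=None, dtype=np.float32):
        super().__init__()
        if order not in ("conv_relu_bn", "conv_bn_relu"):
            raise ValueError(f"unknown order {order!r}")
        self.order = order
        self.conv = Conv(dim, in_channels, width, 3, rng=rng, dtype=dtype)
        self.bn = BatchNorm(width, dtype=dtype)
        self.relu = ReLU()

    def forward(self, x, target):
        from .nn import nearest_resize
        src = x.shape[2:]
        if any(t < s for t, s in zip(target, src)):
            raise ValueError(
                f"UpConv cannot downsample: source {src}, target {tuple(target)}")
        h = self.conv(x)
        if self.order == "conv_relu_bn":
            h = self.bn(self.relu(h))
        else:
            h = self.relu(self.bn(h))
        self._src = h.shape[2:]
        return nearest_resize(h, tuple(target))

    def backward(self, gy):
        from .nn import nearest_resize_adjoint
        g = nearest_resize_adjoint(gy, self._src)
        if self.order == "conv_relu_bn":
            g = self.relu.backward(self.bn.backward(g))
        else:
            g = self.bn.backward(self.relu.backward(g))
        return self.conv.backward(g)


class DoubleConv(Module):
    """Two consecutive (kernel-3 conv, BN, ReLU) blocks.

    Channel-preserving by default; an explicit ``out_channels`` gives the
    classic U-style decoder block shape (C_in -> C_out -> C_out).
    """

    def __init__(self, dim, channels, out_channels=None, *, rng=None,
                 dtype=np.float32):
        super().__init__()
        from .nn import Sequential
        out = channels if out_channels is None else out_channels
        self.body = Sequential(
            Conv(dim, channels, out, 3, rng=rng, dtype=dtype),
            BatchNorm(out, dtype=dtype), ReLU(),
            Conv(dim, out, out, 3, rng=rng, dtype=dtype),
            BatchNorm(out, dtype=dtype), ReLU())

    def forward(self, x):
        return self.body(x)

    def backward(self, gy):
        return self.body.backward(gy)


class SqueezeExcite(Module):
    """Global-average squeeze, two pointwise FC layers, sigmoid channel gate.

    ``gate=False`` bypasses the gating (gate identically 1), used to verify
    that the surrounding block then reduces to its plain conv path.
    """

    def __init__(self, dim, channels, *, reduction=4, gate=True, rng=None,
                 dtype=np.float32):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.dim = dim
        self.gate = gate
        self.fc1 = Conv(dim, channels, hidden, 1, bias=True, rng=rng,
                        dtype=dtype)
        self.fc2 = Conv(dim, hidden, channels, 1, bias=True, rng=rng,
                        dtype=dtype)
        self.relu = ReLU()

    def forward(self, x):
        if not self.gate:
            return x
        axes = tuple(range(2, x.ndim))
        s = x.mean(axis=axes, keepdims=True)
        g = 1.0 / (1.0 + np.exp(-self.fc2(self.relu(self.fc1(s)))))
        self._x, self._g = x, g
        return x * g

    def backward(self, gy):
        if not self.gate:
            return gy
        x, g = self._x, self._g
        axes = tuple(range(2, x.ndim))
        gx = gy * g
        gg = (gy * x).sum(axis=axes, keepdims=True)
        gz = gg * g * (1.0 - g)
        gs = self.fc1.backward(self.relu.backward(self.fc2.backward(gz)))
        npix = int(np.prod(x.shape[2:]))
        return gx + gs / npix


class SEBasicConv(Module):
    """SE channel gating followed by a kernel-3 conv with BN and ReLU."""

    def __init__(self, dim, channels, *, gate=True, rng=None, dtype=np.float32):
        super().__init__()
        self.se = SqueezeExcite(dim, channels, gate=gate, rng=rng, dtype=dtype)
        self.conv = Conv(dim, channels, channels, 3, rng=rng, dtype=dtype)
        self.bn = BatchNorm(channels, dtype=dtype)
        self.relu = ReLU()

    def forward(self, x):
        return self.relu(self.bn(self.conv(self.se(x))))

    def backward(self, gy):
        return self.se.backward(self.conv.backward(self.bn.backward(
            self.relu.backward(gy))))


REFINEMENT_KINDS = ("mlkconv", "doubleconv", "se_basicconv", "none")


def make_refinement(dim, channels, kind, *, rng=None, dtype=np.float32):
    """Build the post-aggregation refinement block named in the config."""
    if kind == "mlkconv":
        return MLKConv(dim, channels, rng=rng, dtype=dtype)
    if kind == "doubleconv":
        return DoubleConv(dim, channels, rng=rng, dtype=dtype)
    if kind == "se_basicconv":
        return SEBasicConv(dim, channels, rng=rng, dtype=dtype)
    if kind == "none":
        return Identity()
    raise ValueError(
        f"unknown refinement kind {kind!r}; choose from {REFINEMENT_KINDS}")


def _gconv_params(cin, cout, k, dim):
    # pointwise cin*cout + depthwise k^dim*cout + batch norm 2*cout
    return cin * cout + (k ** dim + 2) * cout


def count_params(spec: BlockSpec) -> int:
    """Closed-form learnable-entry count of a block.

    For 2D these are the separable-convolution budgets
    ``C_in*C_out + (k^2+2)*C_out`` (GConv), ``C_in*C_out + 11*C_out`` (DConv,
    independent of the dilation rate) and ``4*C^2 + 70*C`` (MLKConv); the 3D
    forms replace ``k^2`` by ``k^3``.  Guaranteed (and tested) to equal the
    enumerated parameter count of an instantiated block.
    """
    cin, cout, dim = spec.in_channels, spec.out_channels, spec.dim
    if spec.kind == "gconv":
        return _gconv_params(cin, cout, spec.kernel, dim)
    if spec.kind == "dconv":
        return _gconv_params(cin, cout, 3, dim)
    if spec.kind == "mlkconv":
        c, c4 = cin, cin // 4
        total = sum(_gconv_params(c, c4, k, dim) for k in MLK_KERNELS)
        total += _gconv_params(c, c, 1, dim)
        total += sum(_gconv_params(c, c4, 3, dim) for _ in MLK_DILATIONS)
        total += _gconv_params(c, c, 1, dim)
        return total
    raise ValueError(f"no closed-form count for kind {spec.kind!r}")


def instantiate(spec: BlockSpec, *, rng=None) -> Module:
    """Build the block a :class:`BlockSpec` describes (enumeration oracle)."""
    if spec.kind == "gconv":
        return GConv(spec.dim, spec.in_channels, spec.out_channels,
                     spec.kernel, dilation=spec.dilation, rng=rng)
    if spec.kind == "dconv":
        return DConv(spec.dim, spec.in_channels, spec.out_channels,
                     spec.dilation, rng=rng)
    if spec.kind == "mlkconv":
        return MLKConv(spec.dim, spec.in_channels, rng=rng)
    if spec.kind == "doubleconv":
        return DoubleConv(spec.dim, spec.in_channels, rng=rng)
    if spec.kind == "se_basicconv":
        return SEBasicConv(spec.dim, spec.in_channels, rng=rng)
    if spec.kind == "upconv":
        return UpConv(spec.dim, spec.in_channels, spec.out_channels, rng=rng)
    raise ValueError(f"unknown kind {spec.kind!r}")
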