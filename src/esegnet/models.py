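"""E-structure model assembly.

An E-model taps every stage of a multi-scale encoder, brings each tapped
stage to input resolution with an :class:`~esegnet.blocks.UpConv`, sums the
results element-wise, refines the sum (MLKConv by default) and classifies
with a kernel-1 head.  There is no progressive decoder: the whole "decoder"
is the aggregation head, which is what makes the design parameter-lean.

Encoders are pluggable; anything emitting a :class:`StagePyramid` that
passes :func:`verify_contract` can be "E-ified" via :func:`e_ify`.
"""

from __future__ import annotations

from math import lcm

import numpy as np

from .blocks import DoubleConv, UpConv, make_refinement
from .nn import BatchNorm, Conv, Module, ModuleList, ReLU, Sequential
from .types import EncoderStageSpec, FeatureMap, StagePyramid

__all__ = [
    "StagedEncoder", "ToyEncoder2D", "ToyEncoder3D", "build_encoder",
    "register_encoder", "verify_contract", "EModel", "e_ify", "MirrorDecoder",
]


class StagedEncoder(Module):
    """Encoder contract: ordered stages with known strides and widths."""

    dim: int
    in_channels: int
    stage_specs: list

    def forward_pyramid(self, x) -> StagePyramid:  # pragma: no cover
        raise NotImplementedError

    def backward_pyramid(self, stage_grads):  # pragma: no cover
        raise NotImplementedError

    def stage_indices(self):
        return [s.index for s in self.stage_specs]


class _ConvStageEncoder(StagedEncoder):
    """Shared machinery for the strided-convolution reference encoders."""

    def __init__(self):
        super().__init__()
        self.stages = ModuleList()

    def forward_pyramid(self, x):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"encoder expects {self.in_channels} input channels, got "
                f"{x.shape[1]}")
        feats = []
        h = x
        for stage in self.stages:
            h = stage(h)
            feats.append(h)
        maps = [FeatureMap(f, spec.stride)
                for f, spec in zip(feats, self.stage_specs)]
        return StagePyramid(maps, self.stage_specs)

    def backward_pyramid(self, stage_grads):
        g = None
        for stage, gs in zip(reversed(list(self.stages)),
                             reversed(list(stage_grads))):
            total = gs if g is None else (g if gs is None else g + gs)
            if total is None:
                # deeper than the deepest tapped stage: nothing flows back
                g = None
                continue
            g = stage.backward(total)
        return g


class ToyEncoder2D(_ConvStageEncoder):
    """Five stride-2 conv stages (strides 2..32), the 2D reference encoder."""

    def __init__(self, widths=(16, 24, 32, 48, 64), in_channels=1, *,
                 rng=None, dtype=np.float32):
        super().__init__()
        if len(widths) != 5:
            raise ValueError(f"2D contract needs 5 stage widths, got {widths}")
        self.dim = 2
        self.in_channels = in_channels
        cin = in_channels
        self.stage_specs = []
        for i, w in enumerate(widths):
            self.stages.append(Sequential(
                Conv(2, cin, w, 3, stride=2, padding=1, rng=rng, dtype=dtype),
                BatchNorm(w, dtype=dtype), ReLU()))
            self.stage_specs.append(
                EncoderStageSpec(i + 1, (2 ** (i + 1),) * 2, w))
            cin = w


class ToyEncoder3D(_ConvStageEncoder):
    """3D reference encoder: patch embedding at stride (4,4,2), one
    shape-preserving stage, then in-plane halvings; the slice axis stays at
    stride 2 throughout."""

    def __init__(self, widths=(16, 24, 32, 48, 64), in_channels=1, *,
                 rng=None, dtype=np.float32):
        super().__init__()
        if len(widths) != 5:
            raise ValueError(f"3D contract needs 5 stage widths, got {widths}")
        self.dim = 3
        self.in_channels = in_channels
        self.stage_specs = []
        # stage 1: non-overlapping 4x4x2 patch projection
        self.stages.append(Sequential(
            Conv(3, in_channels, widths[0], (4, 4, 2), stride=(4, 4, 2),
                 padding=0, rng=rng, dtype=dtype),
            BatchNorm(widths[0], dtype=dtype), ReLU()))
        self.stage_specs.append(EncoderStageSpec(1, (4, 4, 2), widths[0]))
        # stage 2 keeps the resolution; stages 3-5 halve in-plane only
        strides = [(4, 4, 2), (8, 8, 2), (16, 16, 2), (32, 32, 2)]
        cin = widths[0]
        for i, (w, st) in enumerate(zip(widths[1:], strides)):
            s = (1, 1, 1) if i == 0 else (2, 2, 1)
            self.stages.append(Sequential(
                Conv(3, cin, w, 3, stride=s, padding=1, rng=rng, dtype=dtype),
                BatchNorm(w, dtype=dtype), ReLU()))
            self.stage_specs.append(EncoderStageSpec(i + 2, st, w))
            cin = w


_ENCODERS = {}


def register_encoder(name, factory):
    _ENCODERS[name] = factory


register_encoder("toy2d", ToyEncoder2D)
register_encoder("toy3d", ToyEncoder3D)


def verify_contract(encoder: StagedEncoder, input_spatial=None) -> None:
    """Dry-run the encoder on a small input and check every stage's stride
    and channel metadata against the emitted features."""
    if input_spatial is None:
        per_axis = [lcm(*[s.stride[a] for s in encoder.stage_specs])
                    for a in range(encoder.dim)]
        input_spatial = tuple(2 * d for d in per_axis)
    x = np.zeros((1, encoder.in_channels) + tuple(input_spatial), np.float32)
    was_training = encoder.training
    encoder.eval()
    try:
        pyr = encoder.forward_pyramid(x)
    finally:
        encoder.train(was_training)
    pyr.validate(tuple(input_spatial))
    for prev, cur in zip(encoder.stage_specs, encoder.stage_specs[1:]):
        for a in range(encoder.dim - (1 if encoder.dim == 3 else 0)):
            if cur.stride[a] < prev.stride[a]:
                raise ValueError(
                    f"stage {cur.index}: in-plane stride decreases "
                    f"({prev.stride} -> {cur.stride})")


def build_encoder(name, *, rng=None, **options) -> StagedEncoder:
    """Instantiate a named encoder and verify the stage contract."""
    if name not in _ENCODERS:
        raise ValueError(
            f"unknown encoder {name!r}; available: {sorted(_ENCODERS)}. "
            "Pretrained image/video backbones are not bundled with this "
            "package; register one with register_encoder().")
    enc = _ENCODERS[name](rng=rng, **options)
    verify_contract(enc)
    return enc


class EModel(Module):
    """E-structure segmentation network over a staged encoder."""

    def __init__(self, encoder: StagedEncoder, num_classes, *,
                 aggregation_width=64, stage_subset=None,
                 refinement="mlkconv", upconv_order="conv_relu_bn",
                 rng=None, dtype=np.float32):
        super().__init__()
        if num_classes < 2:
            raise ValueError("need at least 2 classes")
        if aggregation_width % 4:
            raise ValueError("aggregation_width must be divisible by 4")
        self.encoder = encoder
        self.dim = encoder.dim
        self.num_classes = num_classes
        self.aggregation_width = aggregation_width
        avail = encoder.stage_indices()
        if stage_subset is None:
            stage_subset = avail if self.dim == 2 else [i for i in avail if i != 1]
        subset = sorted(set(int(i) for i in stage_subset))
        if not subset:
            raise ValueError("stage_subset must not be empty")
        if not set(subset) <= set(avail):
            raise ValueError(
                f"stage_subset {subset} outside encoder stages {avail}")
        self.stage_subset = tuple(subset)
        self.upconvs = ModuleList()
        for idx in self.stage_subset:
            spec = next(s for s in encoder.stage_specs if s.index == idx)
            self.upconvs.append(UpConv(self.dim, spec.channels,
                                       aggregation_width, order=upconv_order,
                                       rng=rng, dtype=dtype))
        self.refinement_kind = refinement
        self.refine = make_refinement(self.dim, aggregation_width, refinement,
                                      rng=rng, dtype=dtype)
        self.head = Conv(self.dim, aggregation_width, num_classes, 1,
                         bias=True, rng=rng, dtype=dtype)

    # -- legality ----------------------------------------------------------
    def required_divisors(self):
        return tuple(lcm(*[s.stride[a] for s in self.encoder.stage_specs])
                     for a in range(self.dim))

    def check_input(self, x):
        div = self.required_divisors()
        spatial = x.shape[2:]
        if any(e % d for e, d in zip(spatial, div)):
            raise ValueError(
                f"input spatial shape {tuple(spatial)} must be divisible by "
                f"{div} per axis")

    # -- compute -----------------------------------------------------------
    def aggregate(self, pyramid: StagePyramid, target):
        """UpConv every selected stage to ``target`` and sum element-wise."""
        agg = None
        for idx, up in zip(self.stage_subset, self.upconvs):
            y = up(pyramid.stage(idx).values, target)
            agg = y if agg is None else agg + y
        return agg

    def forward(self, x):
        self.check_input(x)
        pyr = self.encoder.forward_pyramid(x)
        agg = self.aggregate(pyr, x.shape[2:])
        return self.head(self.refine(agg))

    def backward(self, gy):
        g = self.refine.backward(self.head.backward(gy))
        n_stages = len(self.encoder.stage_specs)
        stage_grads = [None] * n_stages
        order = {s.index: pos for pos, s in enumerate(self.encoder.stage_specs)}
        for idx, up in zip(self.stage_subset, self.upconvs):
            gs = up.backward(g)
            pos = order[idx]
            stage_grads[pos] = gs if stage_grads[pos] is None \
                else stage_grads[pos] + gs
        return self.encoder.backward_pyramid(stage_grads)

    def predict_labels(self, x):
        """Argmax class map (lowest index wins ties, per np.argmax)."""
        was_training = self.training
        self.eval()
        try:
            logits = self.forward(x)
        finally:
            self.train(was_training)
        return np.argmax(logits, axis=1)

    # -- accounting --------------------------------------------------------
    def head_num_params(self) -> int:
        """Learnable entries of the aggregation head (everything that is not
        the encoder): UpConvs + refinement + classifier."""
        n = sum(u.num_params() for u in self.upconvs)
        return n + self.refine.num_params() + self.head.num_params()


def e_ify(encoder: StagedEncoder, num_classes, **kwargs) -> EModel:
    """Turn any contract-satisfying staged encoder into an E-model."""
    verify_contract(encoder)
    return EModel(encoder, num_classes, **kwargs)


class _UpStep(Module):
    """Nearest 2x-style resize to an explicit resolution + kernel-3 conv."""

    def __init__(self, dim, cin, cout, *, rng=None, dtype=np.float32):
        super().__init__()
        self.conv = Conv(dim, cin, cout, 3, rng=rng, dtype=dtype)
        self.bn = BatchNorm(cout, dtype=dtype)
        self.relu = ReLU()

    def forward(self, x, target):
        from .nn import nearest_resize
        self._src = x.shape[2:]
        return self.relu(self.bn(self.conv(nearest_resize(x, target))))

    def backward(self, gy):
        from .nn import nearest_resize_adjoint
        g = self.conv.backward(self.bn.backward(self.relu.backward(gy)))
        return nearest_resize_adjoint(g, self._src)


class MirrorDecoder(Module):
    """A symmetric U-style decoder matched to an encoder's stage widths:
    at each level, upsample to the skip resolution, compress, concatenate
    the skip, and run a DoubleConv; finish with a full-resolution head.
    Used as the parameter-budget comparator for the E-structure head."""

    def __init__(self, encoder: StagedEncoder, num_classes, *, rng=None,
                 dtype=np.float32):
        super().__init__()
        self.encoder_specs = list(encoder.stage_specs)
        self.dim = encoder.dim
        widths = [s.channels for s in self.encoder_specs]
        self.upsteps = ModuleList()
        self.blocks = ModuleList()
        for lo in reversed(range(len(widths) - 1)):
            hi = lo + 1
            self.upsteps.append(_UpStep(self.dim, widths[hi], widths[lo],
                                        rng=rng, dtype=dtype))
            self.blocks.append(DoubleConv(self.dim, 2 * widths[lo], widths[lo],
                                          rng=rng, dtype=dtype))
        self.final_up = _UpStep(self.dim, widths[0], widths[0], rng=rng,
                                dtype=dtype)
        self.head = Conv(self.dim, widths[0], num_classes, 1, bias=True,
                         rng=rng, dtype=dtype)

    def forward(self, pyramid: StagePyramid, target):
        x = pyramid.stages[-1].values
        skips = [fm.values for fm in pyramid.stages[:-1]]
        for up, block, skip in zip(self.upsteps, self.blocks, reversed(skips)):
            x = up(x, skip.shape[2:])
            x = block(np.concatenate([x, skip], axis=1))
        return self.head(self.final_up(x, target))
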