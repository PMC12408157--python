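"""Minimal layer-graph neural-network core.

Layers are NumPy-backed modules with explicit ``forward``/``backward``
methods (Caffe-style).  Each module caches whatever it needs from the
forward pass; ``backward`` consumes the gradient w.r.t. its output,
accumulates gradients into its :class:`Parameter` objects and returns the
gradient w.r.t. its input.  Composite blocks with branching topology
(residual sums, channel concatenation, pyramid aggregation) implement the
two passes by hand.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Parameter", "Module", "ModuleList", "Sequential", "Identity", "ReLU"]


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter(shape={self.data.shape})"


class Module:
    """Base class: auto-registers sub-modules, parameters and buffers."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        """Update a registered buffer in place of the attribute."""
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def modules(self):
        yield self
        for m in self._mods.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for n, m in self._mods.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield (prefix + n, b)
        for n, m in self._mods.items():
            yield from m.named_buffers(prefix + n + ".")

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- mode --------------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({"buf:" + n: np.asarray(b).copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        for n, p in self.named_parameters():
            p.data[...] = state[n]
        self._load_buffers(state, "")

    def _load_buffers(self, state: dict, prefix: str) -> None:
        for n in list(self._buffers):
            key = "buf:" + prefix + n
            if key in state:
                self._set_buffer(n, state[key].copy())
        for n, m in self._mods.items():
            m._load_buffers(state, prefix + n + ".")

    # -- compute -----------------------------------------------------------
    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)

    def forward(self, *args, **kw):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._mods[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x

    def backward(self, gy):
        for m in reversed(list(self.layers)):
            gy = m.backward(gy)
        return gy


class Identity(Module):
    def forward(self, x):
        return x

    def backward(self, gy):
        return gy


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0)
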