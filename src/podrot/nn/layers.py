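"""Neural-network layers for the detector, built on the autograd engine.

The vocabulary mirrors the CSP-style detection family: ``ConvBNSiLU``,
bottleneck ``C3`` stages, ``SPPF`` pooling, nearest upsampling, and the
shuffle-attention block ``SALayer``. Every layer is a ``Module`` exposing
``parameters()`` and a ``train``/``eval`` flag.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module", "ConvBNSiLU", "Bottleneck", "C3", "SPPF", "SALayer",
    "Upsample", "bce_with_logits",
]


class Module:
    """Minimal module base: recursive parameter discovery and mode switching."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list, seen: set) -> None:
        for v in self.__dict__.values():
            self._collect_value(v, params, seen)

    @staticmethod
    def _collect_value(v, params: list, seen: set) -> None:
        if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
            seen.add(id(v))
            params.append(v)
        elif isinstance(v, Module):
            v._collect(params, seen)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._collect_value(item, params, seen)

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for v in self.__dict__.values():
            self._set_training_value(v, mode)

    @staticmethod
    def _set_training_value(v, mode: bool) -> None:
        if isinstance(v, Module):
            v.set_training(mode)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._set_training_value(item, mode)

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)

    # -- state dict (flat arrays, for checkpointing) --------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        self._state(out, "")
        return out

    def _state(self, out: dict, prefix: str) -> None:
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                v._state(out, key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._state(out, f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item.data

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        self._state_refs(own, "")
        for k, arr in state.items():
            tgt = own.get(k)
            if tgt is None:
                continue
            if isinstance(tgt, Tensor):
                tgt.data = np.asarray(arr, dtype=np.float32).reshape(tgt.data.shape)
            else:  # plain ndarray (running stats): patch in place via parent
                tgt[...] = np.asarray(arr).reshape(tgt.shape)

    def _state_refs(self, out: dict, prefix: str) -> None:
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, (Tensor, np.ndarray)):
                out[key] = v
            elif isinstance(v, Module):
                v._state_refs(out, key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._state_refs(out, f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item


def _kaiming(rng: np.random.Generator, cout: int, cin: int, k: int) -> np.ndarray:
    fan_in = cin * k * k
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = self.c
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[:] = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var[:] = (1 - m) * self.running_var + m * var.data.reshape(c)
            xn = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xn = (x - Tensor(mu)) / Tensor(sd)
        return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ConvBNSiLU(Module):
    """k x k convolution + batch norm + SiLU."""

    def __init__(self, cin: int, cout: int, k: int = 1, s: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = k, s, (k - 1) // 2
        self.weight = Tensor(_kaiming(rng, cout, cin, k), requires_grad=True)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(x.conv2d(self.weight, None, stride=self.s, padding=self.p)).silu()


class Bottleneck(Module):
    def __init__(self, cin: int, cout: int, shortcut: bool = True,
                 rng: np.random.Generator | None = None):
        ch = cout // 2
        self.cv1 = ConvBNSiLU(cin, ch, 1, 1, rng)
        self.cv2 = ConvBNSiLU(ch, cout, 3, 1, rng)
        self.add = shortcut and cin == cout

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """CSP bottleneck stage with three 1x1 projections and n inner bottlenecks."""

    def __init__(self, cin: int, cout: int, n: int = 1, shortcut: bool = True,
                 rng: np.random.Generator | None = None):
        ch = cout // 2
        self.cv1 = ConvBNSiLU(cin, ch, 1, 1, rng)
        self.cv2 = ConvBNSiLU(cin, ch, 1, 1, rng)
        self.cv3 = ConvBNSiLU(2 * ch, cout, 1, 1, rng)
        self.m = [Bottleneck(ch, ch, shortcut, rng) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.cv1(x)
        for b in self.m:
            y1 = b(y1)
        y2 = self.cv2(x)
        return self.cv3(concat([y1, y2], axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained k x k max pools."""

    def __init__(self, cin: int, cout: int, k: int = 5,
                 rng: np.random.Generator | None = None):
        ch = cin // 2
        self.k = k
        self.cv1 = ConvBNSiLU(cin, ch, 1, 1, rng)
        self.cv2 = ConvBNSiLU(ch * 4, cout, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.cv1(x)
        p = self.k // 2
        y1 = x.maxpool2d(self.k, 1, p)
        y2 = y1.maxpool2d(self.k, 1, p)
        y3 = y2.maxpool2d(self.k, 1, p)
        return self.cv2(concat([x, y1, y2, y3], axis=1))


class SALayer(Module):
    """Shuffle-attention block (autograd form, trainable gates).

    Matches :func:`podrot.attention.sa_forward` exactly when given the same
    affine parameters: per-group channel/spatial sigmoid gates followed by a
    channel shuffle with ``groups`` groups.
    """

    GN_EPS = 1e-5

    def __init__(self, channels: int, groups: int = 16):
        if channels % (2 * groups) != 0:
            raise ValueError(
                f"channels ({channels}) must be divisible by 2*groups ({2 * groups})"
            )
        self.channels = channels
        self.groups = groups
        half = channels // (2 * groups)
        shp = (groups, half)
        self.channel_scale = Tensor(np.ones(shp, np.float32), requires_grad=True)
        self.channel_shift = Tensor(np.zeros(shp, np.float32), requires_grad=True)
        self.spatial_scale = Tensor(np.ones(shp, np.float32), requires_grad=True)
        self.spatial_shift = Tensor(np.zeros(shp, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        per = c // g
        half = per // 2
        outs = []
        for gi in range(g):
            lo = gi * per
            xc = x[:, lo : lo + half]
            xs = x[:, lo + half : lo + per]
            cs = self.channel_scale[gi].reshape(1, half, 1, 1)
            cb = self.channel_shift[gi].reshape(1, half, 1, 1)
            gate_c = (xc.mean(axis=(2, 3), keepdims=True) * cs + cb).sigmoid()
            outs.append(xc * gate_c)
            ss = self.spatial_scale[gi].reshape(1, half, 1, 1)
            sb = self.spatial_shift[gi].reshape(1, half, 1, 1)
            mu = xs.mean(axis=(1, 2, 3), keepdims=True)
            var = ((xs - mu) ** 2).mean(axis=(1, 2, 3), keepdims=True)
            xn = (xs - mu) / ((var + self.GN_EPS) ** 0.5)
            gate_s = (xn * ss + sb).sigmoid()
            outs.append(xs * gate_s)
        y = concat(outs, axis=1)
        # channel shuffle with g groups
        return (
            y.reshape(n, g, per, h, w).transpose(0, 2, 1, 3, 4).reshape(n, c, h, w)
        )


class Upsample(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.upsample2x()


def bce_with_logits(logits: Tensor, targets: np.ndarray | Tensor) -> Tensor:
    """Numerically stable binary cross-entropy on logits; returns the mean."""
    t = targets if isinstance(targets, Tensor) else Tensor(targets)
    absx = logits.maximum(-logits)
    loss = logits.clamp_min(0.0) - logits * t + ((-absx).exp() + 1.0).log()
    return loss.mean()
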