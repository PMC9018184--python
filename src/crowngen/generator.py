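"""Encoder-decoder generator with a multi-rate dilated bottleneck.

The conditioning stack (preparation, opposing tooth, morphology mask, gap
distance) is downsampled by strided convolutions to 1/4 resolution,
processed by four serial dilated Conv-BN-LeakyReLU blocks whose feature
maps are concatenated channel-wise and fused, then upsampled back by
transposed convolutions to a sigmoid-normalized occlusal-surface image.
Only the defect region is synthesized: the output is composited as
``gen * mask + input * (1 - mask)``.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from ._channels import N_COND_CHANNELS
from .nn import BatchNorm2D, Conv2D, ConvTranspose2D, LeakyReLU, Sequential, Sigmoid


class ConstructionError(ValueError):
    pass


@dataclasses.dataclass
class GeneratorSpec:
    in_channels: int = N_COND_CHANNELS
    base_filters: int = 64
    downsample_stages: int = 2
    dilation_rates: tuple = (1, 2, 4, 8)
    kernel_size: int = 3
    out_channels: int = 1
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.downsample_stages < 1:
            raise ConstructionError("downsample_stages must be >= 1")
        if not self.dilation_rates or any(r <= 0 for r in self.dilation_rates):
            raise ConstructionError("dilation_rates must be positive")
        self.dilation_rates = tuple(int(r) for r in self.dilation_rates)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "GeneratorSpec":
        d = json.loads(s)
        d["dilation_rates"] = tuple(d["dilation_rates"])
        return cls(**d)


def dilated_receptive_field(rates, kernel: int) -> int:
    """Theoretical receptive field of a serial dilated stack:
    1 + sum_i r_i * (kernel - 1)."""
    rates = list(rates)
    if not rates:
        raise ValueError("need at least one dilation rate")
    return 1 + sum(r * (kernel - 1) for r in rates)


def _cbr(in_ch, out_ch, k, stride, dilation, slope, rng):
    return Sequential(
        Conv2D(in_ch, out_ch, k, stride=stride, dilation=dilation, rng=rng),
        BatchNorm2D(out_ch),
        LeakyReLU(slope),
    )


class Generator:
    """The trainable generator; see module docstring for the wiring."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f, k, s = spec.base_filters, spec.kernel_size, spec.leaky_slope

        chans = [spec.in_channels]
        for i in range(spec.downsample_stages + 1):
            chans.append(f * 2**i)
        # stem at full resolution, then stride-2 stages
        self.encoder = [
            _cbr(chans[0], chans[1], k, 1, 1, s, rng)
        ] + [
            _cbr(chans[i + 1], chans[i + 2], k, 2, 1, s, rng)
            for i in range(spec.downsample_stages)
        ]
        bott = chans[-1]
        self.dilated = [
            _cbr(bott, bott, k, 1, r, s, rng) for r in spec.dilation_rates
        ]
        self.fuse = _cbr(bott * len(spec.dilation_rates), bott, 1, 1, 1, s, rng)
        self.decoder = [
            Sequential(
                ConvTranspose2D(chans[i + 2], chans[i + 1], 4, 2, 1, rng=rng),
                BatchNorm2D(chans[i + 1]),
                LeakyReLU(s),
            )
            for i in reversed(range(spec.downsample_stages))
        ]
        self.head = Sequential(
            Conv2D(chans[1], spec.out_channels, 1, rng=rng), Sigmoid()
        )
        self._modules = (
            self.encoder + self.dilated + [self.fuse] + self.decoder + [self.head]
        )

    # -- plumbing ----------------------------------------------------------

    def parameters(self):
        out = []
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def zero_grad(self):
        for m in self._modules:
            m.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def state(self) -> dict:
        return {
            f"m{i}.{k}": v
            for i, m in enumerate(self._modules)
            for k, v in m.state().items()
        }

    def load_state(self, st: dict) -> None:
        for i, m in enumerate(self._modules):
            sub = {k.split(".", 1)[1]: v for k, v in st.items() if k.startswith(f"m{i}.")}
            m.load_state(sub)

    def save(self, path) -> None:
        np.savez(path, __spec__=np.bytes_(self.spec.to_json().encode()), **self.state())

    @classmethod
    def load(cls, path) -> "Generator":
        data = np.load(path)
        spec = GeneratorSpec.from_json(bytes(data["__spec__"]).decode())
        g = cls(spec)
        g.load_state({k: data[k] for k in data.files if k != "__spec__"})
        return g

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ConstructionError(
                f"expected (N, {self.spec.in_channels}, H, W) input, got {x.shape}"
            )
        h = x.astype(np.float32)
        for m in self.encoder:
            h = m.forward(h, train)
        feats = []
        for m in self.dilated:
            h = m.forward(h, train)
            feats.append(h)
        h = np.concatenate(feats, axis=1)
        h = self.fuse.forward(h, train)
        for m in self.decoder:
            h = m.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dy)
        for m in reversed(self.decoder):
            dy = m.backward(dy)
        dy = self.fuse.backward(dy)
        bott = self.spec.base_filters * 2**self.spec.downsample_stages
        # split the concat gradient back to the serial dilated chain
        chunks = [
            dy[:, i * bott : (i + 1) * bott] for i in range(len(self.dilated))
        ]
        grad = np.zeros_like(chunks[-1])
        for m, chunk in zip(reversed(self.dilated), reversed(chunks)):
            grad = m.backward(grad + chunk)
        for m in reversed(self.encoder):
            grad = m.backward(grad)
        return grad


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    """Construct a seeded generator network from its spec."""
    return Generator(spec, seed=seed)


def composite(gen_out: np.ndarray, input_image: np.ndarray, defect_mask) -> np.ndarray:
    """Paint the generated surface only inside the defect region."""
    m = np.asarray(defect_mask, dtype=gen_out.dtype)
    return gen_out * m + input_image * (1.0 - m)


def generate(network: Generator, input_stack: np.ndarray, defect_mask=None) -> np.ndarray:
    """Single inference pass; composites with the preparation channel when a
    defect mask is supplied. Accepts (C, H, W) or (N, C, H, W)."""
    single = input_stack.ndim == 3
    x = input_stack[None] if single else input_stack
    if x.shape[1] != network.spec.in_channels:
        raise ConstructionError(
            f"input has {x.shape[1]} channels, spec wants {network.spec.in_channels}"
        )
    out = network.forward(x.astype(np.float32), train=False)[:, 0]
    if defect_mask is not None:
        m = np.asarray(defect_mask, dtype=out.dtype)
        if m.ndim == 2:
            m = m[None]
        out = out * m + x[:, 0] * (1.0 - m)
    return out[0] if single else out
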