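"""Dual global/local discriminative model.

The global branch judges the whole scene (preparation, opposing tooth,
morphology mask, gap distance, plus the real or generated crown image) with
5x5 stride-2 convolutions; the local branch judges the defect crop with
exactly five convolutional layers and a fully connected layer. Each branch
ends in a feature vector; a fusion head concatenates both vectors into one
real/fake probability. Per-branch sigmoid heads are also exposed so the
adversarial objective can be computed as a sum over the two discriminators
(the default), with fused-probability training available as a switch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import (
    BatchNorm2D,
    Conv2D,
    Dense,
    Flatten,
    LeakyReLU,
    Sequential,
    Sigmoid,
)

EPS = 1e-7  # probabilities are clipped away from {0, 1} before any log


class InferenceError(ValueError):
    pass


@dataclasses.dataclass
class DiscriminatorSpec:
    global_in_channels: int = 5
    local_in_channels: int = 5
    global_kernel: int = 5
    global_stride: int = 2
    local_layers: int = 5
    feature_dim: int = 128
    base_filters: int = 16
    image_size: int = 64
    local_size: int = 32
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        for name in ("global_kernel", "global_stride", "local_layers",
                     "feature_dim", "base_filters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class _Branch:
    """Conv trunk -> flatten -> dense feature vector, plus a sigmoid head."""

    def __init__(self, in_ch, n_layers, k, stride, size, f, feature_dim, slope, rng):
        layers = []
        ch = in_ch
        s = size
        for i in range(n_layers):
            out = min(f * 2**i, 4 * f)
            layers.append(Conv2D(ch, out, k, stride=stride, rng=rng))
            if i > 0:
                layers.append(BatchNorm2D(out))
            layers.append(LeakyReLU(slope))
            ch = out
            s = (s + 2 * ((k - 1) // 2) - k) // stride + 1
        if s < 1:
            raise InferenceError("too many stride-2 layers for the input size")
        self.n_convs = n_layers
        self.trunk = Sequential(*layers)
        self.flat = Flatten()
        self.fc = Dense(ch * s * s, feature_dim, rng=rng)
        self.act = LeakyReLU(slope)
        self.head = Sequential(Dense(feature_dim, 1, rng=rng), Sigmoid())

    def features(self, x, train=True):
        h = self.trunk.forward(x, train)
        return self.act.forward(self.fc.forward(self.flat.forward(h, train), train), train)

    def features_backward(self, dfeat):
        dy = self.act.backward(dfeat)
        return self.trunk.backward(self.flat.backward(self.fc.backward(dy)))

    def trunk_feature_maps(self, x, train=False):
        """Per-conv-layer activations (for the perceptual loss)."""
        maps, h = [], x
        for layer in self.trunk.layers:
            h = layer.forward(h, train)
            if isinstance(layer, LeakyReLU):
                maps.append(h)
        return maps

    def parameters(self):
        return (
            self.trunk.parameters()
            + self.fc.parameters()
            + self.head.parameters()
        )

    def modules(self):
        return [self.trunk, self.fc, self.head]


class DualDiscriminator:
    """Global + local branches with per-branch and fused probability heads."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        n_global = max(1, int(np.log2(spec.image_size)) - 2)
        self.global_branch = _Branch(
            spec.global_in_channels, n_global, spec.global_kernel,
            spec.global_stride, spec.image_size, spec.base_filters,
            spec.feature_dim, spec.leaky_slope, rng,
        )
        self.local_branch = _Branch(
            spec.local_in_channels, spec.local_layers, spec.global_kernel,
            spec.global_stride, spec.local_size, spec.base_filters,
            spec.feature_dim, spec.leaky_slope, rng,
        )
        self.fusion = Sequential(Dense(2 * spec.feature_dim, 1, rng=rng), Sigmoid())

    # -- plumbing ----------------------------------------------------------

    def parameters(self):
        return (
            self.global_branch.parameters()
            + self.local_branch.parameters()
            + self.fusion.parameters()
        )

    def zero_grad(self):
        for _, g in self.parameters():
            g[...] = 0.0

    def _all_modules(self):
        return (
            self.global_branch.modules()
            + self.local_branch.modules()
            + [self.fusion]
        )

    def state(self):
        return {
            f"m{i}.{k}": v
            for i, m in enumerate(self._all_modules())
            for k, v in m.state().items()
        }

    def load_state(self, st):
        for i, m in enumerate(self._all_modules()):
            sub = {k.split(".", 1)[1]: v for k, v in st.items() if k.startswith(f"m{i}.")}
            m.load_state(sub)

    # -- scoring -----------------------------------------------------------

    def _check(self, x, n_ch, name):
        if x.ndim != 4 or x.shape[1] != n_ch:
            raise InferenceError(
                f"{name} stack must be (N, {n_ch}, H, W), got {x.shape}"
            )

    def global_score(self, stack, train=True):
        """P(real) for the full-context stack (x1, c1, c2, d, crown)."""
        self._check(stack, self.spec.global_in_channels, "global")
        feat = self.global_branch.features(stack.astype(np.float32), train)
        self._g_feat_cached = train
        return self.global_branch.head.forward(feat, train)[:, 0]

    def global_backward(self, dprob):
        dfeat = self.global_branch.head.backward(dprob[:, None])
        return self.global_branch.features_backward(dfeat)

    def local_score(self, stack, train=True):
        """P(real) for the defect-crop stack (x1', c1', c3, d', crown')."""
        self._check(stack, self.spec.local_in_channels, "local")
        feat = self.local_branch.features(stack.astype(np.float32), train)
        return self.local_branch.head.forward(feat, train)[:, 0]

    def local_backward(self, dprob):
        dfeat = self.local_branch.head.backward(dprob[:, None])
        return self.local_branch.features_backward(dfeat)

    def fused_score(self, global_stack, local_stack, train=True,
                    zero_local: bool = False):
        """Joint P(real) from the concatenated branch features.

        ``zero_local`` ablates the local branch's contribution (used to
        assert that both branches influence the decision).
        """
        self._check(global_stack, self.spec.global_in_channels, "global")
        self._check(local_stack, self.spec.local_in_channels, "local")
        fg = self.global_branch.features(global_stack.astype(np.float32), train)
        fl = self.local_branch.features(local_stack.astype(np.float32), train)
        if zero_local:
            fl = np.zeros_like(fl)
        return self.fusion.forward(np.concatenate([fg, fl], axis=1), train)[:, 0]

    def fused_backward(self, dprob):
        dfeat = self.fusion.backward(dprob[:, None])
        k = self.spec.feature_dim
        dg = self.global_branch.features_backward(dfeat[:, :k])
        dl = self.local_branch.features_backward(dfeat[:, k:])
        return dg, dl


def build_dual_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> DualDiscriminator:
    return DualDiscriminator(spec, seed=seed)


# ---------------------------------------------------------------------------
# adversarial objective


def _clip(p):
    return np.clip(p, EPS, 1.0 - EPS)


def bce_real(p):
    """(-log p, d/dp) for samples that should be judged real."""
    p = _clip(p)
    return float(np.mean(-np.log(p))), -1.0 / (p * p.size)


def bce_fake(p):
    """(-log(1-p), d/dp) for samples that should be judged fake."""
    p = _clip(p)
    return float(np.mean(-np.log(1.0 - p))), 1.0 / ((1.0 - p) * p.size)


def generator_adv_loss(p_fake):
    """Non-saturating generator loss (-log D(fake)) and its d/dp."""
    p = _clip(p_fake)
    return float(np.mean(-np.log(p))), -1.0 / (p * p.size)


def adversarial_objectives(p_real_global, p_fake_global, p_real_local, p_fake_local):
    """Scalar adversarial losses summed over the two discriminators.

    Returns (loss_G_adv, loss_D): the discriminator term is
    -[log D_k(real) + log(1 - D_k(fake))] and the generator term is the
    non-saturating -log D_k(fake), each summed over k in {global, local}.
    """
    loss_d = 0.0
    loss_g = 0.0
    for p_real, p_fake in (
        (p_real_global, p_fake_global),
        (p_real_local, p_fake_local),
    ):
        pr = _clip(np.asarray(p_real, dtype=np.float64))
        pf = _clip(np.asarray(p_fake, dtype=np.float64))
        loss_d += float(np.mean(-np.log(pr)) + np.mean(-np.log(1.0 - pf)))
        loss_g += float(np.mean(-np.log(pf)))
    return loss_g, loss_d
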