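"""Composite loss and the three-stage training schedule.

The total objective is

    L_total = L_adv + lambda_L1 * L_L1 + lambda_mse * L_mse + lambda_per * L_per

with default weights 100 / 50 / 50 and Adam(lr=2e-4, beta1=0.5,
beta2=0.999). Training complexity grows in stages: the generator is first
trained alone with L1 plus masked occlusion/morphology constraint terms
(Stage I); then it is frozen while the two discriminators train from
scratch against it, with MSE and perceptual losses logged for monitoring
(Stage II); finally generator and both discriminators train jointly on the
full objective (Stage III).
"""

from __future__ import annotations

import dataclasses
import csv
from pathlib import Path

import numpy as np

from .discriminators import (
    DualDiscriminator,
    bce_fake,
    bce_real,
    generator_adv_loss,
    adversarial_objectives,
)
from .generator import Generator, composite
from .nn import Adam, BatchNorm2D, Conv2D, LeakyReLU
from .nn import ops


class LossError(ValueError):
    pass


class TrainingAborted(RuntimeError):
    """Raised on divergence; the last good state stays on the networks."""


@dataclasses.dataclass
class LossWeights:
    lambda_L1: float = 100.0
    lambda_mse: float = 50.0
    lambda_per: float = 50.0
    occlusion: float = 1.0
    morphology: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lambda_L1, self.lambda_mse, self.lambda_per,
               self.occlusion, self.morphology) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclasses.dataclass
class TrainConfig:
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    leaky_slope: float = 0.2
    stage_epochs: tuple = (5, 5, 10)
    batch_size: int = 4
    seed: int = 0
    stage2_literal: bool = False
    fused_adversarial: bool = False

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if any(e < 0 for e in self.stage_epochs):
            raise ValueError("stage epochs must be >= 0")
        self.stage_epochs = tuple(int(e) for e in self.stage_epochs)


# ---------------------------------------------------------------------------
# pixel losses


def _check_shapes(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise LossError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse_loss(gen, target) -> float:
    """Squared Frobenius norm of the difference, normalized by pixel count."""
    g, t = _check_shapes(gen, target)
    return float(np.mean((g - t) ** 2))


def l1_loss(gen, target) -> float:
    """Mean absolute difference."""
    g, t = _check_shapes(gen, target)
    return float(np.mean(np.abs(g - t)))


def masked_l1(gen, target, mask) -> float:
    """Mean absolute difference restricted to mask == 1 pixels."""
    g, t = _check_shapes(gen, target)
    m = np.broadcast_to(np.asarray(mask, dtype=np.float64), g.shape)
    n = m.sum()
    if n == 0:
        return 0.0
    return float((np.abs(g - t) * m).sum() / n)


def perceptual_loss(gen, target, feature_net) -> float:
    """Sum over tagged layers of the mean L1 feature distance.

    ``feature_net`` is any callable returning the list of intermediate
    feature maps for an input; each term is normalized by its own C*H*W.
    """
    g, t = _check_shapes(gen, target)
    maps_g = feature_net(g)
    maps_t = feature_net(t)
    if not maps_g:
        raise LossError("feature_net exposes no tagged feature maps")
    return float(
        sum(np.mean(np.abs(a - b)) for a, b in zip(maps_g, maps_t))
    )


def total_loss(adv, l1, mse, per, w: LossWeights | None = None) -> float:
    """Weighted sum L_adv + lambda_L1*L1 + lambda_mse*MSE + lambda_per*Lper."""
    w = w or LossWeights()
    for name, v in (("adv", adv), ("l1", l1), ("mse", mse), ("per", per)):
        if not np.isfinite(v):
            raise LossError(f"non-finite loss component: {name}")
    return float(adv + w.lambda_L1 * l1 + w.lambda_mse * mse + w.lambda_per * per)


# ---------------------------------------------------------------------------
# perceptual path with private caches (frozen-trunk features + input grad)


class PerceptualPath:
    """Forward/backward through a frozen conv trunk with local caches.

    Batch-norm layers are treated as fixed affine maps (running statistics),
    so evaluating the perceptual loss never perturbs the discriminator.
    """

    def __init__(self, trunk):
        self.layers = trunk.layers

    def forward(self, x):
        caches, maps = [], []
        h = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            if isinstance(layer, Conv2D):
                y, cols = ops.conv2d(
                    h, layer.w, layer.b, layer.stride, layer.dilation,
                    layer.pad, return_cols=True,
                )
                caches.append(("conv", layer, h.shape[2:]))
                h = y
            elif isinstance(layer, BatchNorm2D):
                inv = 1.0 / np.sqrt(layer.run_var + layer.eps)
                h = (
                    layer.gamma[None, :, None, None]
                    * (h - layer.run_mean[None, :, None, None])
                    * inv[None, :, None, None]
                    + layer.beta[None, :, None, None]
                )
                caches.append(("bn", layer, inv))
            elif isinstance(layer, LeakyReLU):
                mask = h >= 0
                h = np.where(mask, h, layer.slope * h)
                caches.append(("lrelu", layer, mask))
                maps.append(h)
            else:  # pragma: no cover - trunk only contains the above
                raise LossError(f"unsupported layer in feature net: {layer}")
        self._caches = caches
        return maps

    def backward(self, dmaps):
        """Input gradient given one gradient array per tagged feature map."""
        dmaps = list(dmaps)
        dy = None
        for kind, layer, aux in reversed(self._caches):
            if kind == "lrelu":
                dmap = dmaps.pop()
                dy = dmap if dy is None else dy + dmap
                dy = np.where(aux, dy, layer.slope * dy)
            elif kind == "bn":
                dy = dy * (layer.gamma * aux)[None, :, None, None]
            else:  # conv
                dy = ops.conv2d_input_grad(
                    dy, layer.w, aux, layer.stride, layer.dilation, layer.pad
                )
        return dy

    def __call__(self, x):
        return self.forward(x)


def _perceptual_value_and_grad(path: PerceptualPath, gen_stack, target_stack):
    maps_g = path.forward(gen_stack)
    # target features via a throwaway path so gen caches survive
    tmp = PerceptualPath.__new__(PerceptualPath)
    tmp.layers = path.layers
    maps_t = tmp.forward(target_stack)
    value = float(sum(np.mean(np.abs(a - b)) for a, b in zip(maps_g, maps_t)))
    dmaps = [np.sign(a - b) / a.size for a, b in zip(maps_g, maps_t)]
    dx = path.backward(dmaps)
    return value, dx


# ---------------------------------------------------------------------------
# staged training


@dataclasses.dataclass
class TrainResult:
    log: list
    val_log: list
    checkpoints: dict
    aborted: bool = False

    def write_csv(self, path) -> None:
        path = Path(path)
        with path.open("w", newline="") as f:
            wtr = csv.DictWriter(
                f,
                fieldnames=[
                    "iteration", "stage", "loss_l1", "loss_mse",
                    "loss_per", "loss_adv", "loss_d",
                ],
            )
            wtr.writeheader()
            for row in self.log:
                wtr.writerow(row)


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _stack_batch(cases, idx):
    x = np.stack([cases[i].input_stack for i in idx]).astype(np.float32)
    z = np.stack([cases[i].target_global for i in idx]).astype(np.float32)
    mask = np.stack([cases[i].defect_mask for i in idx]).astype(np.float32)
    return x, z, mask


def _local_crop_batch(cases, idx, images):
    return np.stack(
        [cases[i].crop_local(images[j]) for j, i in enumerate(idx)]
    ).astype(np.float32)


def _local_cond_batch(cases, idx):
    return np.stack([cases[i].local_input_stack for i in idx]).astype(np.float32)


def _scatter_local_grad(cases, idx, dlocal, shape):
    """Adjoint of the nearest-neighbour local crop."""
    out = np.zeros(shape, dtype=np.float32)
    for j, i in enumerate(idx):
        np.add.at(
            out[j],
            (cases[i].local_rows[:, None], cases[i].local_cols[None, :]),
            dlocal[j],
        )
    return out


def _with_crown(cond, crown):
    return np.concatenate([cond, crown[:, None]], axis=1)


def _check_finite(loss, name):
    if not np.isfinite(loss) or abs(loss) > 1e4:
        raise TrainingAborted(f"divergence in {name}: {loss}")


def train_staged(
    train_cases,
    val_cases,
    generator: Generator,
    discriminator: DualDiscriminator,
    cfg: TrainConfig | None = None,
    weights: LossWeights | None = None,
    out_dir: str | Path | None = None,
) -> TrainResult:
    """Run the three-stage schedule; returns per-iteration logs and
    stage-boundary checkpoints (in memory, plus .npz files if out_dir set)."""
    cfg = cfg or TrainConfig()
    w = weights or LossWeights()
    rng = np.random.default_rng(cfg.seed)
    log, val_log, checkpoints = [], [], {}
    result = TrainResult(log, val_log, checkpoints)
    if sum(cfg.stage_epochs) == 0:
        return result

    opt_g = Adam(generator.parameters(), cfg.lr, cfg.beta1, cfg.beta2)
    opt_d = Adam(discriminator.parameters(), cfg.lr, cfg.beta1, cfg.beta2)
    path = PerceptualPath(discriminator.global_branch.trunk)
    it = 0
    n = len(train_cases)

    def g_forward_composite(x, mask, train):
        raw = generator.forward(x, train=train)[:, 0]
        return raw * mask + x[:, 0] * (1.0 - mask)

    def eval_val_l1():
        tot = []
        for c in val_cases:
            out = g_forward_composite(
                c.input_stack[None].astype(np.float32),
                c.defect_mask[None].astype(np.float32),
                train=False,
            )
            tot.append(l1_loss(out[0], c.target_global))
        return tot

    def monitor_losses(x, z, comp, idx):
        """mse/perceptual on the current batch (logging only)."""
        mse = mse_loss(comp, z)
        gstack = _with_crown(x, comp)
        rstack = _with_crown(x, z)
        per = perceptual_loss(gstack, rstack, path)
        return mse, per

    def d_step(x, z, mask, idx):
        """One discriminator update against the (possibly frozen) generator."""
        comp = g_forward_composite(x, mask, train=False)
        real_g = _with_crown(x, z)
        fake_g = _with_crown(x, comp)
        lc = _local_cond_batch(train_cases, idx)
        real_l = _with_crown(lc, _local_crop_batch(train_cases, idx, z))
        fake_l = _with_crown(lc, _local_crop_batch(train_cases, idx, comp))
        discriminator.zero_grad()
        loss_d = 0.0
        if cfg.fused_adversarial:
            pr = discriminator.fused_score(real_g, real_l, train=True)
            lr_, dpr = bce_real(pr)
            discriminator.fused_backward(dpr)
            pf = discriminator.fused_score(fake_g, fake_l, train=True)
            lf, dpf = bce_fake(pf)
            discriminator.fused_backward(dpf)
            loss_d = lr_ + lf
        else:
            for score, back, real, fake in (
                (discriminator.global_score, discriminator.global_backward,
                 real_g, fake_g),
                (discriminator.local_score, discriminator.local_backward,
                 real_l, fake_l),
            ):
                p = score(real, train=True)
                lv, dp = bce_real(p)
                back(dp)
                loss_d += lv
                p = score(fake, train=True)
                lv, dp = bce_fake(p)
                back(dp)
                loss_d += lv
        _check_finite(loss_d, "discriminator loss")
        opt_d.step()
        return loss_d, comp

    def checkpoint(name):
        checkpoints[name] = {
            "generator": {k: v.copy() for k, v in generator.state().items()},
            "discriminator": {
                k: v.copy() for k, v in discriminator.state().items()
            },
        }
        if out_dir is not None:
            od = Path(out_dir)
            od.mkdir(parents=True, exist_ok=True)
            generator.save(od / f"generator_{name}.npz")
            np.savez(od / f"discriminator_{name}.npz", **discriminator.state())

    try:
        # ---- Stage I: generator alone, L1 + constraint terms -------------
        for epoch in range(cfg.stage_epochs[0]):
            for idx in _batches(n, cfg.batch_size, rng):
                x, z, mask = _stack_batch(train_cases, idx)
                generator.zero_grad()
                comp = g_forward_composite(x, mask, train=True)
                diff = comp - z
                l1 = float(np.mean(np.abs(diff)))
                fmask = np.stack(
                    [train_cases[i].fingerprint_mask for i in idx]
                ).astype(np.float32)
                gmask = np.stack(
                    [train_cases[i].groove_mask for i in idx]
                ).astype(np.float32)
                occ = masked_l1(comp, z, fmask.astype(bool))
                mor = masked_l1(comp, z, gmask.astype(bool))
                loss = w.lambda_L1 * l1 + w.occlusion * occ + w.morphology * mor
                _check_finite(loss, "stage-I generator loss")
                dcomp = w.lambda_L1 * np.sign(diff) / diff.size
                if fmask.sum():
                    dcomp += w.occlusion * np.sign(diff) * fmask / fmask.sum()
                if gmask.sum():
                    dcomp += w.morphology * np.sign(diff) * gmask / gmask.sum()
                generator.backward((dcomp * mask)[:, None].astype(np.float32))
                opt_g.step()
                mse, per = monitor_losses(x, z, comp, idx)
                log.append(
                    dict(iteration=it, stage=1, loss_l1=l1, loss_mse=mse,
                         loss_per=per, loss_adv=float("nan"),
                         loss_d=float("nan"))
                )
                it += 1
            if val_cases:
                val_log.append(
                    dict(stage=1, epoch=epoch,
                         median_l1=float(np.median(eval_val_l1())))
                )
        checkpoint("stage1")
        g_frozen = {k: v.copy() for k, v in generator.state().items()}

        # ---- Stage II: discriminators from scratch vs frozen generator ---
        for epoch in range(cfg.stage_epochs[1]):
            for idx in _batches(n, cfg.batch_size, rng):
                x, z, mask = _stack_batch(train_cases, idx)
                loss_d, comp = d_step(x, z, mask, idx)
                l1 = l1_loss(comp, z)
                mse, per = monitor_losses(x, z, comp, idx)
                if cfg.stage2_literal:
                    # literal reading: the monitored MSE/perceptual terms are
                    # folded into the reported discriminator objective
                    loss_d = loss_d + w.lambda_mse * mse + w.lambda_per * per
                p_fake_g = discriminator.global_score(
                    _with_crown(x, comp), train=False
                )
                adv = float(np.mean(-np.log(np.clip(p_fake_g, 1e-7, 1))))
                log.append(
                    dict(iteration=it, stage=2, loss_l1=l1, loss_mse=mse,
                         loss_per=per, loss_adv=adv, loss_d=loss_d)
                )
                it += 1
        # generator must be bit-identical across Stage II
        for k, v in generator.state().items():
            if not np.array_equal(v, g_frozen[k]):
                raise TrainingAborted("generator changed during Stage II")
        checkpoint("stage2")

        # ---- Stage III: joint adversarial training ------------------------
        for epoch in range(cfg.stage_epochs[2]):
            for idx in _batches(n, cfg.batch_size, rng):
                x, z, mask = _stack_batch(train_cases, idx)
                loss_d, _ = d_step(x, z, mask, idx)

                generator.zero_grad()
                discriminator.zero_grad()  # scratch space for the G pass
                raw = generator.forward(x, train=True)[:, 0]
                comp = raw * mask + x[:, 0] * (1.0 - mask)
                diff = comp - z
                l1 = float(np.mean(np.abs(diff)))
                mse = float(np.mean(diff**2))
                dcomp = (
                    w.lambda_L1 * np.sign(diff) / diff.size
                    + w.lambda_mse * 2.0 * diff / diff.size
                )

                gstack = _with_crown(x, comp)
                rstack = _with_crown(x, z)
                per, dper_stack = _perceptual_value_and_grad(path, gstack, rstack)
                dcomp += w.lambda_per * dper_stack[:, -1]

                lc = _local_cond_batch(train_cases, idx)
                comp_l = _local_crop_batch(train_cases, idx, comp)
                lstack = _with_crown(lc, comp_l)
                if cfg.fused_adversarial:
                    p = discriminator.fused_score(gstack, lstack, train=True)
                    adv, dp = generator_adv_loss(p)
                    dg_stack, dl_stack = discriminator.fused_backward(dp)
                    dcomp += dg_stack[:, -1]
                    dcomp += _scatter_local_grad(
                        train_cases, idx, dl_stack[:, -1], comp.shape
                    )
                else:
                    p_g = discriminator.global_score(gstack, train=True)
                    adv_g, dp_g = generator_adv_loss(p_g)
                    dg_stack = discriminator.global_backward(dp_g)
                    dcomp += dg_stack[:, -1]
                    p_l = discriminator.local_score(lstack, train=True)
                    adv_l, dp_l = generator_adv_loss(p_l)
                    dl_stack = discriminator.local_backward(dp_l)
                    dcomp += _scatter_local_grad(
                        train_cases, idx, dl_stack[:, -1], comp.shape
                    )
                    adv = adv_g + adv_l
                tot = total_loss(adv, l1, mse, per, w)
                _check_finite(tot, "stage-III total loss")
                generator.backward((dcomp * mask)[:, None].astype(np.float32))
                opt_g.step()
                log.append(
                    dict(iteration=it, stage=3, loss_l1=l1, loss_mse=mse,
                         loss_per=per, loss_adv=adv, loss_d=loss_d)
                )
                it += 1
            if val_cases:
                val_log.append(
                    dict(stage=3, epoch=epoch,
                         median_l1=float(np.median(eval_val_l1())))
                )
        checkpoint("stage3")
    except TrainingAborted:
        result.aborted = True
        raise
    return result
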