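"""Scikit-learn style estimator facade over the adversarial inpainter.

``OcclusalInpainter`` wraps network construction, the three-stage training
schedule and masked inference behind the familiar fit/predict/score API so
the model composes with sklearn model selection; the underlying modules
(:mod:`crowngen.generator`, :mod:`crowngen.discriminators`,
:mod:`crowngen.objectives`) remain directly usable.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .discriminators import DiscriminatorSpec, DualDiscriminator
from .generator import Generator, GeneratorSpec
from .metrics import psnr
from .objectives import LossWeights, TrainConfig, train_staged


class OcclusalInpainter(BaseEstimator):
    """Dual-discriminator adversarial model for occlusal-surface completion.

    Parameters mirror the network/training configuration; all fitted state
    lives in trailing-underscore attributes. ``X`` is a sequence of
    :class:`crowngen.synthetic.CaseSample`; targets ride along inside the
    cases, so ``y`` is ignored.
    """

    def __init__(
        self,
        base_filters: int = 16,
        dilation_rates: tuple = (1, 2, 4, 8),
        kernel_size: int = 3,
        feature_dim: int = 64,
        disc_filters: int = 8,
        stage_epochs: tuple = (5, 5, 10),
        batch_size: int = 4,
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        lambda_l1: float = 100.0,
        lambda_mse: float = 50.0,
        lambda_per: float = 50.0,
        fused_adversarial: bool = False,
        random_state: int = 0,
    ):
        self.base_filters = base_filters
        self.dilation_rates = dilation_rates
        self.kernel_size = kernel_size
        self.feature_dim = feature_dim
        self.disc_filters = disc_filters
        self.stage_epochs = stage_epochs
        self.batch_size = batch_size
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.lambda_l1 = lambda_l1
        self.lambda_mse = lambda_mse
        self.lambda_per = lambda_per
        self.fused_adversarial = fused_adversarial
        self.random_state = random_state

    def _validate_cases(self, X):
        X = list(X)
        if not X:
            raise ValueError("need at least one case")
        shape = X[0].input_stack.shape
        for c in X:
            if c.input_stack.shape != shape:
                raise ValueError("cases disagree in stack shape")
        return X

    def fit(self, X, y=None, validation_cases=None):
        X = self._validate_cases(X)
        h, w = X[0].input_stack.shape[1:]
        hl = X[0].local_input_stack.shape[1]
        gen_spec = GeneratorSpec(
            base_filters=self.base_filters,
            dilation_rates=tuple(self.dilation_rates),
            kernel_size=self.kernel_size,
        )
        disc_spec = DiscriminatorSpec(
            feature_dim=self.feature_dim,
            base_filters=self.disc_filters,
            image_size=h,
            local_size=hl,
        )
        self.generator_ = Generator(gen_spec, seed=self.random_state + 1)
        self.discriminator_ = DualDiscriminator(
            disc_spec, seed=self.random_state + 2
        )
        cfg = TrainConfig(
            lr=self.lr,
            beta1=self.beta1,
            beta2=self.beta2,
            stage_epochs=tuple(self.stage_epochs),
            batch_size=self.batch_size,
            seed=self.random_state + 3,
            fused_adversarial=self.fused_adversarial,
        )
        weights = LossWeights(
            lambda_L1=self.lambda_l1,
            lambda_mse=self.lambda_mse,
            lambda_per=self.lambda_per,
        )
        self.train_result_ = train_staged(
            X, validation_cases or [], self.generator_, self.discriminator_,
            cfg, weights,
        )
        self.n_iterations_ = len(self.train_result_.log)
        return self

    def predict(self, X) -> np.ndarray:
        """Composited occlusal-surface images, shape (n_cases, H, W)."""
        if not hasattr(self, "generator_"):
            raise AttributeError("OcclusalInpainter is not fitted yet")
        X = self._validate_cases(X)
        out = []
        for c in X:
            raw = self.generator_.forward(
                c.input_stack[None].astype(np.float32), train=False
            )[0, 0]
            m = c.defect_mask.astype(np.float32)
            out.append(raw * m + c.input_stack[0] * (1.0 - m))
        return np.stack(out)

    def score(self, X, y=None) -> float:
        """Mean PSNR (dB, peak=1 on normalized images) against the targets."""
        X = self._validate_cases(X)
        preds = self.predict(X)
        return float(
            np.mean([psnr(p, c.target_global, peak=1.0) for p, c in zip(preds, X)])
        )
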