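"""Training: SSL pre-training, supervised transfer pre-training, and
two-step fine-tuning, all with AdamW and a warmup–cosine schedule.

Pre-training minimizes the masked-patch reconstruction MSE for 5×10⁴ steps
at peak learning rate 1e-4, weight decay 0.01, batch size 64 (published scale;
the desk-scale tests use far fewer steps).  Fine-tuning is two-step: the
GRF head alone is trained first (encoder frozen, lr 1e-3, 300 steps), then
the whole model (lr 1e-4, 300 steps), which protects the pre-trained
representations from early distortion.  No early stopping, no gradient
clipping.  All randomness (batch order, masks, dropout, init) derives from
a single seed, so runs are exactly reproducible on one device.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .data import NormalizationStats, WindowSet
from .errors import AnnotationError, ConfigError, ValidationError
from .layout import CANONICAL_SENSORS
from .model import ModelConfig, PatchMaskedTransformer
from .nn.autograd import Tensor
from .nn.optim import AdamW
from .preprocessing import WindowNormalizer, apply_normalizer


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (AdamW with decoupled weight decay)."""

    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 64
    total_steps: int = 50_000
    warmup_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.warmup_fraction < 1:
            raise ConfigError(f"warmup_fraction {self.warmup_fraction} outside (0, 1)")
        if self.total_steps < 1:
            raise ConfigError("total_steps must be >= 1")


def lr_at(step: int, cfg: TrainConfig) -> float:
    """Learning rate at 0-based *step*: linear ramp to peak over the first
    20% of steps (first step already nonzero), then cosine decay to ~0."""
    if not 0 <= step < cfg.total_steps:
        raise ConfigError(f"step {step} outside [0, {cfg.total_steps})")
    warmup = max(1, int(round(cfg.warmup_fraction * cfg.total_steps)))
    if step < warmup:
        return cfg.learning_rate * (step + 1) / warmup
    remainder = max(1, cfg.total_steps - warmup)
    progress = (step - warmup) / remainder
    return cfg.learning_rate * 0.5 * (1.0 + np.cos(np.pi * progress))


def _batch_indices(n: int, batch_size: int, total_steps: int,
                   rng: np.random.Generator):
    """Yield per-step index arrays: shuffled without replacement per epoch,
    reshuffled each epoch."""
    order = rng.permutation(n)
    pos = 0
    for _ in range(total_steps):
        if pos >= n:
            order = rng.permutation(n)
            pos = 0
        yield order[pos : pos + batch_size]
        pos += batch_size


def sample_batch_masks(n_windows: int, n_patches: int, ratio: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Fresh uniform-without-replacement mask per window: boolean
    (n_windows, n_patches) with exactly round(ratio·n_patches) True each."""
    n_masked = int(np.floor(ratio * n_patches + 0.5))
    if n_masked == 0:
        raise ConfigError("masking ratio rounds to zero masked patches")
    scores = rng.random((n_windows, n_patches))
    idx = np.argsort(scores, axis=1)[:, :n_masked]
    mask = np.zeros((n_windows, n_patches), dtype=bool)
    np.put_along_axis(mask, idx, True, axis=1)
    return mask


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# SSL pre-training
# ---------------------------------------------------------------------------

class MaskedPatchPretrainer(BaseEstimator):
    """Self-supervised pre-trainer: mask random patches, reconstruct them.

    ``fit`` expects an already-normalized unlabeled :class:`WindowSet` and
    exposes the trained model as ``model_`` and the per-step loss as
    ``loss_history_``.
    """

    def __init__(self, model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.model_config = model_config
        self.train_config = train_config

    def fit(self, X: WindowSet, y=None) -> "MaskedPatchPretrainer":
        if len(X) == 0:
            raise ValidationError("cannot pre-train on an empty corpus")
        mcfg = self.model_config or ModelConfig()
        tcfg = self.train_config or TrainConfig()
        init_rng, batch_rng, mask_rng, drop_rng = _spawn_rngs(tcfg.seed, 4)
        model = PatchMaskedTransformer(mcfg, rng=init_rng,
                                       with_reconstruction_head=True)
        opt = AdamW(model.parameters(), weight_decay=tcfg.weight_decay)
        valid = X.valid_mask().astype(float)
        history = []
        batches = _batch_indices(len(X), tcfg.batch_size, tcfg.total_steps, batch_rng)
        for step, idx in enumerate(batches):
            mask = sample_batch_masks(len(idx), mcfg.n_patches,
                                      mcfg.masking_ratio, mask_rng)
            loss = model.masked_reconstruction_loss(
                X.data[idx], mask, valid[idx], training=True, rng=drop_rng
            )
            opt.zero_grad()
            loss.backward()
            opt.step(lr_at(step, tcfg))
            history.append(float(loss.data))
        self.model_ = model
        self.loss_history_ = history
        return self


def pretrain_ssl(corpus: WindowSet, model_cfg: ModelConfig,
                 train_cfg: TrainConfig) -> tuple[PatchMaskedTransformer, list[float]]:
    est = MaskedPatchPretrainer(model_cfg, train_cfg).fit(corpus)
    return est.model_, est.loss_history_


def reconstruction_mse(model: PatchMaskedTransformer, X: WindowSet,
                       seed: int = 0) -> float:
    """Masked-patch MSE of *model* on (normalized) held-out windows, with
    dropout disabled and a seeded mask per window."""
    mask = sample_batch_masks(len(X), model.config.n_patches,
                              model.config.masking_ratio,
                              np.random.default_rng(seed))
    loss = model.masked_reconstruction_loss(
        X.data, mask, X.valid_mask().astype(float), training=False
    )
    return float(loss.data)


# ---------------------------------------------------------------------------
# supervised transfer pre-training (Motion Transfer / Task Transfer)
# ---------------------------------------------------------------------------

class SupervisedPretrainer(BaseEstimator):
    """Pre-train the same encoder with a per-patch linear regression head
    (3 outputs per time step) on window-aligned targets, no masking.

    Covers both transfer baselines: real IMU → GRF ("motion transfer") and
    synthetic IMU → body-center acceleration ("task transfer")."""

    def __init__(self, model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.model_config = model_config
        self.train_config = train_config

    def fit(self, X: WindowSet, y: np.ndarray) -> "SupervisedPretrainer":
        if len(X) == 0:
            raise ValidationError("cannot pre-train on an empty corpus")
        y = np.asarray(y, dtype=float)
        if y.shape != (len(X), X.data.shape[1], 3):
            raise ValidationError(
                f"targets shape {y.shape} misaligned with windows "
                f"({len(X)} × {X.data.shape[1]} × 3)"
            )
        mcfg = self.model_config or ModelConfig()
        tcfg = self.train_config or TrainConfig()
        init_rng, batch_rng, _, drop_rng = _spawn_rngs(tcfg.seed, 4)
        model = PatchMaskedTransformer(mcfg, rng=init_rng,
                                       with_reconstruction_head=False,
                                       with_grf_head=True)
        opt = AdamW(model.parameters(), weight_decay=tcfg.weight_decay)
        valid = X.valid_mask().astype(float)
        history = []
        for step, idx in enumerate(
            _batch_indices(len(X), tcfg.batch_size, tcfg.total_steps, batch_rng)
        ):
            loss = _grf_mse(model, X.data[idx], y[idx], valid[idx],
                            training=True, rng=drop_rng)
            opt.zero_grad()
            loss.backward()
            opt.step(lr_at(step, tcfg))
            history.append(float(loss.data))
        self.model_ = model
        self.loss_history_ = history
        return self


def pretrain_supervised(corpus: WindowSet, targets: np.ndarray,
                        model_cfg: ModelConfig, train_cfg: TrainConfig,
                        head_dim: int = 3) -> PatchMaskedTransformer:
    if head_dim != 3:
        raise ConfigError("supervised pre-training heads emit 3 values per step")
    return SupervisedPretrainer(model_cfg, train_cfg).fit(corpus, targets).model_


def _grf_mse(model: PatchMaskedTransformer, windows: np.ndarray,
             targets: np.ndarray, valid_rows: np.ndarray,
             present_sensors: tuple[str, ...] = CANONICAL_SENSORS,
             training: bool = False,
             rng: np.random.Generator | None = None) -> Tensor:
    """MSE over valid rows between predicted and target normalized GRF."""
    x = model.substitute_missing(windows, present_sensors)
    patches = x.reshape(
        windows.shape[0], model.config.n_patches, model.config.patch_dim
    )
    pred = model.predict_grf(model.encode(patches, training, rng))
    weight = np.broadcast_to(valid_rows[..., None], targets.shape).astype(float)
    total = weight.sum()
    diff = pred - Tensor(targets)
    return (diff.square() * Tensor(weight)).sum() * (1.0 / total)


# ---------------------------------------------------------------------------
# two-step fine-tuning
# ---------------------------------------------------------------------------

class GRFRegressor(RegressorMixin, BaseEstimator):
    """3-axis GRF estimator with two-step fine-tuning.

    Parameters
    ----------
    model_config : architecture; must match ``init_model`` when given.
    init_model : a pre-trained :class:`PatchMaskedTransformer` (or checkpoint
        path) whose encoder initializes this model; ``None`` means the
        random-init supervised baseline.  The GRF head is always freshly
        initialized.
    present_sensors : sensors available at input; omitted ones are filled by
        trainable substitution patches.
    head_config / full_config : optimizer settings for step 1 (head only,
        encoder frozen) and step 2 (entire model).
    input_stats : IMU normalization statistics to carry over from
        pre-training.  When fine-tuning a pre-trained encoder, z-scoring the
        inputs with the *pre-training* statistics keeps the encoder's input
        distribution unchanged; refitting them on a small labeled fold
        shifts it and measurably degrades transfer.  GRF statistics are
        always fitted on the training fold.  Ignored (``None``) for the
        random-init baseline.

    ``fit`` takes a labeled raw (un-normalized) :class:`WindowSet`; the
    normalizer is fitted on that training data and ``predict`` returns GRF
    in N/kg.
    """

    def __init__(
        self,
        model_config: ModelConfig | None = None,
        init_model: PatchMaskedTransformer | str | None = None,
        present_sensors: tuple[str, ...] = CANONICAL_SENSORS,
        head_config: TrainConfig | None = None,
        full_config: TrainConfig | None = None,
        input_stats: "NormalizationStats | None" = None,
        seed: int = 0,
    ):
        self.model_config = model_config
        self.init_model = init_model
        self.present_sensors = present_sensors
        self.head_config = head_config
        self.full_config = full_config
        self.input_stats = input_stats
        self.seed = seed

    def _resolve_configs(self) -> tuple[ModelConfig, TrainConfig, TrainConfig]:
        mcfg = self.model_config or ModelConfig()
        head = self.head_config or TrainConfig(learning_rate=1e-3, total_steps=300,
                                               seed=self.seed)
        full = self.full_config or TrainConfig(learning_rate=1e-4, total_steps=300,
                                               seed=self.seed)
        return mcfg, head, full

    def _build_model(self, mcfg: ModelConfig,
                     rng: np.random.Generator) -> PatchMaskedTransformer:
        omitted = tuple(s for s in CANONICAL_SENSORS
                        if s not in tuple(self.present_sensors))
        model = PatchMaskedTransformer(
            mcfg, rng=rng, with_reconstruction_head=False, with_grf_head=True,
            substituted_sensors=omitted,
        )
        source = self.init_model
        if source is not None:
            if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
                source, _ = PatchMaskedTransformer.load(source)
            if source.config != mcfg:
                raise ConfigError(
                    "pre-trained model config does not match model_config"
                )
            src = source.parameters()
            dst = model.encoder_parameters()
            for key, tensor in dst.items():
                if key in src:
                    tensor.data = src[key].data.copy()
        return model

    def fit(self, X: WindowSet, y=None) -> "GRFRegressor":
        if not isinstance(X, WindowSet) or not X.has_grf:
            raise AnnotationError("fine-tuning requires a GRF-labeled WindowSet")
        mcfg, head_cfg, full_cfg = self._resolve_configs()
        init_rng, b1, b2, drop_rng = _spawn_rngs(self.seed, 4)
        normalizer = WindowNormalizer().fit(X)
        if self.input_stats is not None:
            normalizer.stats_ = dataclasses.replace(
                normalizer.stats_,
                imu_mean=np.asarray(self.input_stats.imu_mean, dtype=float),
                imu_std=np.asarray(self.input_stats.imu_std, dtype=float),
            )
        Xn = normalizer.transform(X)
        model = self._build_model(mcfg, init_rng)
        valid = Xn.valid_mask().astype(float)
        present = tuple(self.present_sensors)

        def run(cfg: TrainConfig, params: dict, batch_rng) -> list[float]:
            opt = AdamW(params, weight_decay=cfg.weight_decay)
            history = []
            for step, idx in enumerate(
                _batch_indices(len(Xn), cfg.batch_size, cfg.total_steps, batch_rng)
            ):
                loss = _grf_mse(model, Xn.data[idx], Xn.grf[idx], valid[idx],
                                present, training=True, rng=drop_rng)
                opt.zero_grad()
                loss.backward()
                opt.step(lr_at(step, cfg))
                history.append(float(loss.data))
            return history

        # step 1: GRF head only, encoder (and substitution patches) frozen
        self.loss_history_head_ = run(head_cfg, model.head_parameters(), b1)
        # step 2: entire model
        self.loss_history_full_ = run(full_cfg, model.parameters(), b2)
        self.model_ = model
        self.normalizer_ = normalizer
        return self

    def predict(self, X: WindowSet | np.ndarray) -> np.ndarray:
        """Predict 3-axis GRF (N/kg), shape (n_windows, 128, 3).

        Padded rows (when ``X`` is a WindowSet with short windows) are zeroed.
        """
        stats = self.normalizer_.stats_
        if isinstance(X, WindowSet):
            data = apply_normalizer(X, replace(stats, grf_mean=None, grf_std=None)
                                    if X.grf is None else stats).data
            valid = X.valid_mask()
        else:
            data = (np.asarray(X, dtype=float) - stats.imu_mean) / stats.imu_std
            valid = np.ones(data.shape[:2], dtype=bool)
        model = self.model_
        x = model.substitute_missing(data, tuple(self.present_sensors))
        patches = x.reshape(data.shape[0], model.config.n_patches,
                            model.config.patch_dim)
        pred = model.predict_grf(model.encode(patches, training=False)).data
        pred = pred * stats.grf_std + stats.grf_mean
        return np.where(valid[..., None], pred, 0.0)


def finetune_two_step(
    state: PatchMaskedTransformer | str | None,
    labeled: WindowSet,
    cfg1: TrainConfig | None = None,
    cfg2: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    present_sensors: tuple[str, ...] = CANONICAL_SENSORS,
    input_stats: NormalizationStats | None = None,
    seed: int = 0,
) -> GRFRegressor:
    """Functional wrapper: two-step fine-tuning of a (pre-trained or random)
    model on a labeled WindowSet; returns the fitted regressor."""
    if model_config is None and isinstance(state, PatchMaskedTransformer):
        model_config = state.config
    return GRFRegressor(
        model_config=model_config, init_model=state,
        present_sensors=present_sensors,
        head_config=cfg1, full_config=cfg2,
        input_stats=input_stats, seed=seed,
    ).fit(labeled)
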