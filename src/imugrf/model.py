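"""The patch-masked transformer for IMU windows.

A 128×48 window is sliced into contiguous time patches (patch_length × 48,
flattened), a random subset of patches is replaced by a single trainable mask
patch in raw patch space, each patch is linearly embedded to width 192 with a
fixed sinusoidal positional code added, and six post-norm encoder blocks
produce one embedding per patch.  A per-patch linear head maps embeddings
back to patch space for reconstruction (pre-training) or to 3-axis GRF
(fine-tuning).  Omitted sensors are replaced by per-sensor trainable
substitution patches tiled across time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .data import NormalizationStats
from .errors import ConfigError, ValidationError
from .layout import CANONICAL_SENSORS
from .nn.autograd import Tensor, concat
from .nn.layers import EncoderBlock, Linear, Module, sinusoidal_positions

_CHECKPOINT_VERSION = "imugrf-checkpoint-1"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The published configuration is the default (width 192, six blocks,
    8 heads, 512 feedforward units, 10% dropout, layer-norm eps 1e-5, ReLU);
    ``tiny()`` gives the desk-scale test profile.
    """

    patch_length: int = 1
    masking_ratio: float = 0.125
    embed_dim: int = 192
    n_blocks: int = 6
    n_heads: int = 8
    ff_dim: int = 512
    dropout: float = 0.10
    layer_norm_eps: float = 1e-5
    n_axes: int = 48
    window_length: int = 128

    def __post_init__(self) -> None:
        if self.window_length % self.patch_length:
            raise ConfigError(
                f"window_length {self.window_length} not divisible by "
                f"patch_length {self.patch_length}"
            )
        if self.embed_dim % self.n_heads:
            raise ConfigError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        if not 0 < self.masking_ratio < 1:
            raise ConfigError(f"masking_ratio {self.masking_ratio} outside (0, 1)")

    @property
    def n_patches(self) -> int:
        return self.window_length // self.patch_length

    @property
    def patch_dim(self) -> int:
        return self.patch_length * self.n_axes

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale profile used throughout the test suite."""
        kwargs = dict(patch_length=4, embed_dim=64, n_blocks=2, n_heads=4,
                      ff_dim=128)
        kwargs.update(overrides)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# patch ops (pure numpy; the model reuses the same reshapes in-graph)
# ---------------------------------------------------------------------------

def slice_patches(window: np.ndarray, patch_length: int) -> np.ndarray:
    """(…, 128, 48) → (…, n_patches, patch_length·48), row-major flattening.

    Patch *i* holds rows ``[i·L, (i+1)·L)``; ``unslice_patches`` is its exact
    inverse.
    """
    *lead, n, c = window.shape
    if n % patch_length:
        raise ConfigError(f"{n} samples not divisible by patch_length {patch_length}")
    t = n // patch_length
    return window.reshape(*lead, t, patch_length * c)


def unslice_patches(patches: np.ndarray, patch_length: int, n_axes: int = 48) -> np.ndarray:
    *lead, t, p = patches.shape
    if p != patch_length * n_axes:
        raise ConfigError(f"patch dim {p} != {patch_length}×{n_axes}")
    return patches.reshape(*lead, t * patch_length, n_axes)


def sample_mask(
    n_patches: int, ratio: float, rng: np.random.Generator | int | None
) -> np.ndarray:
    """Exactly ``round(ratio·n_patches)`` distinct patch indices, uniform
    without replacement; raises :class:`ConfigError` if the count rounds to
    zero."""
    if not 0 < ratio < 1:
        raise ConfigError(f"masking ratio {ratio} outside (0, 1)")
    n_masked = int(np.floor(ratio * n_patches + 0.5))
    if n_masked == 0:
        raise ConfigError(
            f"masking ratio {ratio} rounds to zero masked patches of {n_patches}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return np.sort(rng.choice(n_patches, size=n_masked, replace=False))


class PatchMaskedTransformer(Module):
    """Encoder plus trainable mask/substitution patches and output heads.

    Parameters
    ----------
    config : ModelConfig
    rng : seed or Generator for weight initialization.
    with_reconstruction_head, with_grf_head : which per-patch output heads to
        create (pre-training uses reconstruction; fine-tuning uses GRF).
    substituted_sensors : sensors absent from the input whose columns are
        filled by trainable patches.
    """

    def __init__(
        self,
        config: ModelConfig,
        rng: np.random.Generator | int | None = 0,
        with_reconstruction_head: bool = True,
        with_grf_head: bool = False,
        substituted_sensors: tuple[str, ...] = (),
    ) -> None:
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.config = config
        self.substituted_sensors = tuple(substituted_sensors)
        d, p = config.embed_dim, config.patch_dim

        self.add_child("embed", Linear(rng, p, d))
        for i in range(config.n_blocks):
            self.add_child(
                f"block{i}",
                EncoderBlock(rng, d, config.n_heads, config.ff_dim,
                             config.dropout, config.layer_norm_eps),
            )
        self.positional = sinusoidal_positions(config.n_patches, d)  # fixed
        self.mask_patch = self.register("mask_patch",
                                        Tensor(rng.normal(0.0, 0.02, size=p)))
        if with_reconstruction_head:
            self.add_child("recon_head", Linear(rng, d, p))
        if with_grf_head:
            self.add_child("grf_head", Linear(rng, d, config.patch_length * 3))
        for sensor in self.substituted_sensors:
            if sensor not in CANONICAL_SENSORS:
                raise ValidationError(f"unknown sensor {sensor!r}")
            self.register(
                f"sub.{sensor}",
                Tensor(rng.normal(0.0, 0.02, size=config.patch_length * 6)),
            )

    # -- structural queries ------------------------------------------------
    def encoder_parameters(self) -> dict[str, Tensor]:
        """Everything except the output heads (shared across objectives)."""
        return {k: v for k, v in self.parameters().items()
                if not k.startswith(("recon_head", "grf_head"))}

    def head_parameters(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.parameters().items()
                if k.startswith(("recon_head", "grf_head"))}

    # -- forward pieces ----------------------------------------------------
    def apply_mask(self, patches: Tensor | np.ndarray, mask: np.ndarray) -> Tensor:
        """Replace masked patches by the shared trainable mask patch.

        ``mask`` is boolean, shape (batch, n_patches) or (n_patches,);
        masking happens in raw patch space, before linear embedding.
        """
        if not isinstance(patches, Tensor):
            patches = Tensor(patches)
        t = patches.shape[-2]
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask.astype(int)
            if idx.size and (idx.min() < 0 or idx.max() >= t):
                raise ValidationError("mask index out of range")
            m = np.zeros(t, dtype=bool)
            m[idx] = True
            mask = m
        m = mask.astype(float)[..., None]
        return patches * (1.0 - m) + self.mask_patch * m

    def encode(self, patches: Tensor | np.ndarray, training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Linear embed → fixed sinusoidal position code → encoder blocks."""
        if not isinstance(patches, Tensor):
            patches = Tensor(patches)
        if patches.shape[-2] != self.config.n_patches:
            raise ValidationError(
                f"expected {self.config.n_patches} patches, got {patches.shape[-2]}"
            )
        if rng is None:
            rng = np.random.default_rng(0)
        x = self._children["embed"](patches) + Tensor(self.positional)
        for i in range(self.config.n_blocks):
            x = self._children[f"block{i}"](x, training, rng)
        return x

    def reconstruct(self, embeddings: Tensor) -> Tensor:
        """Per-patch linear map back to patch space, unsliced to (…, 128, 48)."""
        cfg = self.config
        patches = self._children["recon_head"](embeddings)
        *lead, t, _ = patches.shape
        return patches.reshape(*lead, cfg.window_length, cfg.n_axes)

    def predict_grf(self, embeddings: Tensor) -> Tensor:
        """Per-patch linear map to normalized GRF, unsliced to (…, 128, 3)."""
        cfg = self.config
        patches = self._children["grf_head"](embeddings)
        *lead, t, _ = patches.shape
        return patches.reshape(*lead, cfg.window_length, 3)

    def substitute_missing(
        self, window: Tensor | np.ndarray, present_sensors: tuple[str, ...]
    ) -> Tensor:
        """Replace the 6 columns of every omitted sensor with its trainable
        substitution patch, tiled across time patches."""
        present = tuple(present_sensors)
        if not present:
            raise ValidationError("at least one sensor must be present")
        unknown = set(present) - set(CANONICAL_SENSORS)
        if unknown:
            raise ValidationError(f"unknown sensors {sorted(unknown)}")
        if not isinstance(window, Tensor):
            window = Tensor(window)
        omitted = [s for s in CANONICAL_SENSORS if s not in present]
        if not omitted:
            return window
        cfg = self.config
        lead = window.shape[:-2]
        parts = []
        for i, sensor in enumerate(CANONICAL_SENSORS):
            cols = slice(i * 6, i * 6 + 6)
            if sensor in present:
                parts.append(window.index_last(cols))
            else:
                key = f"sub.{sensor}"
                if key not in self._params:
                    raise ValidationError(
                        f"model has no substitution patch for {sensor!r}; "
                        f"construct with substituted_sensors including it"
                    )
                patch = self._params[key].reshape(cfg.patch_length, 6)
                tiled = patch.broadcast_to((cfg.n_patches, cfg.patch_length, 6))
                tiled = tiled.reshape(cfg.window_length, 6)
                parts.append(tiled.broadcast_to((*lead, cfg.window_length, 6)))
        return concat(parts, axis=-1)

    # -- losses ------------------------------------------------------------
    def masked_reconstruction_loss(
        self,
        windows: np.ndarray,
        mask: np.ndarray,
        valid_rows: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Mean squared error between reconstruction and the unmasked input
        over exactly the masked-patch entries (padded rows excluded)."""
        cfg = self.config
        patches = slice_patches(windows, cfg.patch_length)
        masked = self.apply_mask(patches, mask)
        recon = self.reconstruct(self.encode(masked, training, rng))
        row_mask = np.repeat(mask.astype(float), cfg.patch_length, axis=-1)
        weight = np.broadcast_to(row_mask[..., None],
                                 windows.shape).astype(float).copy()
        if valid_rows is not None:
            weight *= valid_rows[..., None]
        total = weight.sum()
        if total == 0:
            raise ValidationError("no masked entries to compute a loss over")
        diff = recon - Tensor(windows)
        return (diff.square() * Tensor(weight)).sum() * (1.0 / total)

    # -- persistence -------------------------------------------------------
    def save(self, path, stats: NormalizationStats | None = None) -> None:
        """Checkpoint weights + config (+ normalization stats), bit-exact."""
        arrays = {f"param/{k}": p.data for k, p in self.parameters().items()}
        meta = {
            "version": _CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "substituted_sensors": list(self.substituted_sensors),
            "heads": {
                "reconstruction": "recon_head" in self._children,
                "grf": "grf_head" in self._children,
            },
        }
        if stats is not None:
            arrays["stats/imu_mean"] = stats.imu_mean
            arrays["stats/imu_std"] = stats.imu_std
            if stats.grf_mean is not None:
                arrays["stats/grf_mean"] = stats.grf_mean
                arrays["stats/grf_std"] = stats.grf_std
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(
        cls, path, expected_config: ModelConfig | None = None
    ) -> tuple["PatchMaskedTransformer", NormalizationStats | None]:
        with np.load(path) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            if meta.get("version") != _CHECKPOINT_VERSION:
                raise ValidationError(
                    f"unknown checkpoint version {meta.get('version')!r}"
                )
            config = ModelConfig(**meta["config"])
            if expected_config is not None and config != expected_config:
                raise ConfigError(
                    f"checkpoint config {config} does not match expected "
                    f"{expected_config}"
                )
            model = cls(
                config,
                rng=0,
                with_reconstruction_head=meta["heads"]["reconstruction"],
                with_grf_head=meta["heads"]["grf"],
                substituted_sensors=tuple(meta["substituted_sensors"]),
            )
            params = model.parameters()
            for key, tensor in params.items():
                stored = f[f"param/{key}"]
                if stored.shape != tensor.data.shape:
                    raise ValidationError(f"checkpoint tensor {key} shape mismatch")
                tensor.data = stored.copy()
            stats = None
            if "stats/imu_mean" in f:
                stats = NormalizationStats(
                    imu_mean=f["stats/imu_mean"].copy(),
                    imu_std=f["stats/imu_std"].copy(),
                    grf_mean=f["stats/grf_mean"].copy() if "stats/grf_mean" in f else None,
                    grf_std=f["stats/grf_std"].copy() if "stats/grf_std" in f else None,
                )
        return model, stats


def count_parameters(config: ModelConfig, with_grf_head: bool = False,
                     substituted_sensors: tuple[str, ...] = ()) -> int:
    """Exact count of trainable scalars of the pre-training model (embedding,
    encoder blocks, reconstruction head, mask patch; substitution patches and
    the GRF head only when configured)."""
    model = PatchMaskedTransformer(
        config, rng=0,
        with_reconstruction_head=not with_grf_head,
        with_grf_head=with_grf_head,
        substituted_sensors=substituted_sensors,
    )
    return model.n_parameters()
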