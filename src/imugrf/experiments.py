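"""Higher-level experiments: the masking-ratio × patch-length grid search
and data-efficiency scaling runs, at a configurable compute budget."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import WindowSet
from .errors import ConfigError
from .evaluation import EvalConfig, evaluate_predictions, subsample_indices
from .model import ModelConfig
from .training import GRFRegressor, MaskedPatchPretrainer, TrainConfig

logger = logging.getLogger(__name__)

PATCH_LENGTH_GRID = (1, 2, 4, 8)
MASKING_RATIO_GRID = (0.0625, 0.125, 0.25, 0.375, 0.5, 0.625)


@dataclass(frozen=True)
class GridBudget:
    """Per-cell compute budget (desk scale by default)."""

    pretrain_steps: int = 200
    finetune_steps: int = 100
    batch_size: int = 32
    seed: int = 0


def gridsearch(
    corpus: WindowSet,
    downstream_train: WindowSet,
    downstream_test: WindowSet,
    base_config: ModelConfig | None = None,
    patch_lengths: tuple[int, ...] = PATCH_LENGTH_GRID,
    masking_ratios: tuple[float, ...] = MASKING_RATIO_GRID,
    budget: GridBudget | None = None,
    corpus_stats=None,
) -> dict:
    """Joint grid over patch length and masking ratio.

    Each cell pre-trains with identical seed and budget, fine-tunes on the
    downstream training windows, and records the mean per-participant vGRF
    correlation on the test windows.  A cell whose masked-patch count rounds
    to zero is marked invalid rather than failing the grid.
    """
    base = base_config or ModelConfig.tiny()
    budget = budget or GridBudget()
    table = np.full((len(patch_lengths), len(masking_ratios)), np.nan)
    valid = np.ones_like(table, dtype=bool)
    for i, pl in enumerate(patch_lengths):
        for j, ratio in enumerate(masking_ratios):
            try:
                cfg = ModelConfig(
                    **{**_asdict(base), "patch_length": pl, "masking_ratio": ratio}
                )
                n_masked = int(np.floor(ratio * cfg.n_patches + 0.5))
                if n_masked == 0:
                    raise ConfigError("mask count rounds to zero")
            except ConfigError as exc:
                logger.warning("cell (%s, %s) invalid: %s", pl, ratio, exc)
                valid[i, j] = False
                continue
            tcfg = TrainConfig(total_steps=budget.pretrain_steps,
                               batch_size=budget.batch_size, seed=budget.seed)
            pre = MaskedPatchPretrainer(cfg, tcfg).fit(corpus)
            ft = TrainConfig(learning_rate=1e-3, total_steps=budget.finetune_steps,
                             batch_size=budget.batch_size, seed=budget.seed)
            ft2 = TrainConfig(learning_rate=1e-4, total_steps=budget.finetune_steps,
                              batch_size=budget.batch_size, seed=budget.seed)
            reg = GRFRegressor(model_config=cfg, init_model=pre.model_,
                               head_config=ft, full_config=ft2,
                               input_stats=corpus_stats,
                               seed=budget.seed).fit(downstream_train)
            rep = evaluate_predictions(reg.predict(downstream_test),
                                       downstream_test)
            table[i, j] = rep.mean_correlation()
    if valid.any() and np.isfinite(table[valid]).any():
        flat_best = np.nanargmax(np.where(valid, table, -np.inf))
        bi, bj = np.unravel_index(flat_best, table.shape)
        best = {"patch_length": patch_lengths[bi],
                "masking_ratio": masking_ratios[bj],
                "rho": float(table[bi, bj])}
    else:
        best = None
    return {
        "patch_lengths": list(patch_lengths),
        "masking_ratios": list(masking_ratios),
        "rho": table,
        "valid": valid,
        "best": best,
    }


def scaling_run(
    train: WindowSet,
    test: WindowSet,
    fractions,
    init_model,
    model_config: ModelConfig,
    finetune_steps: int = 100,
    batch_size: int = 32,
    seed: int = 0,
    input_stats=None,
) -> list[tuple[float, float]]:
    """vGRF correlation versus labeled-training fraction (nested subsamples)."""
    out = []
    for frac in fractions:
        idx = subsample_indices(len(train), float(frac), seed)
        sub = train[idx]
        ft1 = TrainConfig(learning_rate=1e-3, total_steps=finetune_steps,
                          batch_size=batch_size, seed=seed)
        ft2 = TrainConfig(learning_rate=1e-4, total_steps=finetune_steps,
                          batch_size=batch_size, seed=seed)
        reg = GRFRegressor(model_config=model_config, init_model=init_model,
                           head_config=ft1, full_config=ft2, seed=seed,
                           input_stats=input_stats if init_model is not None else None,
                           ).fit(sub)
        rep = evaluate_predictions(reg.predict(test), test, EvalConfig())
        out.append((float(frac), rep.mean_correlation()))
    return out


def _asdict(cfg: ModelConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)
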