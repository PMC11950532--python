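"""Sensitivity maps: vanilla input gradients and SmoothGrad, plus the
age-correlation noise calibration.

A sensitivity map is the gradient of the model's predicted age with
respect to every input voxel.  Raw gradient maps are noisy, so SmoothGrad
averages the gradients of many Gaussian-noise-perturbed copies of the
input; the noise standard deviation is a fraction of the volume's dynamic
range.  The working noise level is chosen on a held-out cohort as the
grid level (0%..50% in 2% steps) that maximizes the mean absolute Pearson
correlation between age and per-ROI sensitivity.

Maps are always computed from the *uncorrected* model output: the bias
correction acts on the prediction table downstream and never enters the
gradient path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .io import as_array
from .roi_stats import parcellate

__all__ = [
    "SaliencyConfig",
    "NoiseCalibrationReport",
    "vanilla_gradient",
    "smoothgrad",
    "default_noise_grid",
    "calibrate_noise",
]


@dataclass(frozen=True)
class SaliencyConfig:
    noise_level: float = 0.10   # fraction of the input dynamic range
    n_samples: int = 25
    seed: int = 0
    reduce: str = "signed"      # or "absolute"
    sigma_reference: float | None = None
    """Dynamic-range reference for the noise sigma.

    When None, sigma = noise_level * (max - min) of each volume.  For
    cohort analyses a fixed per-modality reference (e.g. the median
    dynamic range of a healthy calibration cohort) should be supplied:
    per-volume scaling couples the noise amplitude to whatever shifts a
    subject's intensity range — age, pathology — and that coupling leaks
    into every region of the map as a spurious group/age signal.
    """

    def __post_init__(self):
        if not 0.0 <= self.noise_level <= 0.5:
            raise ValueError("noise_level must lie in [0, 0.5]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.reduce not in ("signed", "absolute"):
            raise ValueError(f"unknown reduce mode {self.reduce!r}")
        if self.sigma_reference is not None and self.sigma_reference < 0:
            raise ValueError("sigma_reference must be >= 0")


@dataclass
class NoiseCalibrationReport:
    """Per-level, per-ROI age correlations and the chosen noise level."""

    table: pd.DataFrame          # columns: level, region, r
    scores: pd.Series            # index level, value mean |r| over ROIs
    chosen_level: float
    sigma_reference: float = 0.0  # dynamic-range reference used for sigma

    def __post_init__(self):
        levels = self.scores.index.to_numpy()
        if np.any(np.diff(levels) <= 0):
            raise ValueError("grid levels must be strictly increasing")


def _input_gradient(model: nn.Sequential, batch: np.ndarray) -> np.ndarray:
    out = model.forward(batch)
    if out.ndim != 2 or out.shape[1] != 1:
        raise ValueError(f"model output must be one scalar per input, "
                         f"got shape {out.shape}")
    return model.backward(np.ones_like(out))


def vanilla_gradient(model: nn.Sequential, volume: np.ndarray) -> np.ndarray:
    """Gradient of the predicted age with respect to each input voxel.

    ``volume`` is one input of shape (C, D, H, W); the map has the same
    shape.  Samples in a batch are independent, so the per-sample map
    does not depend on what else is in the batch.
    """
    volume = np.asarray(volume, dtype=np.float64)
    squeeze = volume.ndim == 4
    batch = volume[None] if squeeze else volume
    grad = _input_gradient(model, batch)
    return grad[0] if squeeze else grad


def smoothgrad(model: nn.Sequential, volume: np.ndarray,
               cfg: SaliencyConfig) -> np.ndarray:
    """Average gradient over ``n_samples`` noisy copies of the input.

    Noise is i.i.d. Normal(0, sigma^2) per voxel with
    sigma = noise_level * R, where R is ``cfg.sigma_reference`` when set
    and otherwise this volume's dynamic range (max - min).  In
    ``absolute`` mode each sample map is rectified before averaging.
    Deterministic per seed.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 4:
        raise ValueError(f"expected one (C, D, H, W) volume, got {volume.shape}")
    dyn = (float(volume.max() - volume.min()) if cfg.sigma_reference is None
           else cfg.sigma_reference)
    sigma = cfg.noise_level * dyn
    if cfg.noise_level > 0 and sigma == 0.0:
        warnings.warn("constant input volume: SmoothGrad noise sigma is 0",
                      RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng([int(cfg.seed), 0x5A71])
    batch = np.repeat(volume[None], cfg.n_samples, axis=0)
    if sigma > 0:
        batch += rng.normal(0.0, sigma, batch.shape)
    grads = _input_gradient(model, batch)
    if cfg.reduce == "absolute":
        grads = np.abs(grads)
    return grads.mean(axis=0)


def default_noise_grid() -> np.ndarray:
    """The calibration grid: 0% to 50% of dynamic range in 2% steps."""
    return np.round(np.arange(0, 26) * 0.02, 2)


def _roi_age_correlations(roi: pd.DataFrame, ages: np.ndarray) -> pd.Series:
    """Pearson r(age, ROI sensitivity) per region; 0 where degenerate."""
    a = ages - ages.mean()
    x = roi.to_numpy() - roi.to_numpy().mean(axis=0)
    num = a @ x
    den = np.sqrt((a @ a) * np.einsum("ij,ij->j", x, x))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return pd.Series(r, index=roi.columns)


def calibrate_noise(model: nn.Sequential, volumes: list[np.ndarray],
                    ages: np.ndarray, atlas, grid=None,
                    cfg: SaliencyConfig | None = None) -> NoiseCalibrationReport:
    """Choose the SmoothGrad noise level by the age-correlation criterion.

    For each grid level: compute every calibration subject's SmoothGrad
    map, parcellate it, and correlate each ROI's sensitivity with age.
    The aggregate score of a level is the mean |r| over ROIs; the chosen
    level attains the maximum (ties go to the smallest level).

    Unless the config already fixes one, the noise sigma reference is the
    median dynamic range of the calibration volumes, so every subject
    receives the same noise amplitude at a given level (see
    :class:`SaliencyConfig.sigma_reference`).
    """
    cfg = cfg or SaliencyConfig()
    ages = np.asarray(ages, dtype=float)
    if len(volumes) != len(ages):
        raise ValueError("one age per calibration volume required")
    if len(volumes) < 3:
        raise ValueError("need >= 3 calibration subjects")
    if np.var(ages) == 0:
        raise ValueError("calibration ages have zero variance")
    lab = as_array(atlas)
    for i, v in enumerate(volumes):
        if np.asarray(v).shape[1:] != lab.shape:
            raise ValueError(f"volume {i} spatial grid {np.asarray(v).shape[1:]} "
                             f"does not match atlas grid {lab.shape}")
    grid = default_noise_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid levels must be strictly increasing")
    sigma_ref = cfg.sigma_reference
    if sigma_ref is None:
        sigma_ref = float(np.median([np.max(v) - np.min(v) for v in volumes]))

    rows = []
    scores = {}
    for level in grid:
        roi_rows = []
        for i, vol in enumerate(volumes):
            level_cfg = SaliencyConfig(noise_level=float(level),
                                       n_samples=cfg.n_samples,
                                       seed=int(np.random.SeedSequence(
                                           [cfg.seed, int(round(level * 1000)), i]
                                       ).generate_state(1)[0] % (2 ** 31)),
                                       reduce=cfg.reduce,
                                       sigma_reference=sigma_ref)
            smap = smoothgrad(model, vol, level_cfg)
            # sensitivity summed over channels before parcellation
            roi_rows.append(parcellate(smap.sum(axis=0), atlas))
        roi = pd.DataFrame(roi_rows)
        r = _roi_age_correlations(roi, ages)
        scores[float(level)] = float(np.mean(np.abs(r)))
        for region, val in r.items():
            rows.append({"level": float(level), "region": int(region),
                         "r": float(val)})

    score_series = pd.Series(scores).sort_index()
    best = score_series.max()
    chosen = float(min(lv for lv, s in scores.items() if s == best))
    return NoiseCalibrationReport(table=pd.DataFrame(rows),
                                  scores=score_series, chosen_level=chosen,
                                  sigma_reference=sigma_ref)
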