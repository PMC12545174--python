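"""Encoding-model contract and noise-aware evaluation metrics.

An encoding model maps stimuli to predicted voxel responses (in z-units),
standing in for any trained stimulus-response model.  Evaluation follows
the noise-ceiling framework for repeated-presentation designs:

* NCSNR — the ratio of signal to noise standard deviation, estimated from
  repeats of the same images on z-scored betas,
* the noise ceiling NC(n) = 100 * NCSNR^2 / (NCSNR^2 + 1/n), the maximum
  percentage of response variance any stimulus-driven model can explain
  when n trials are averaged,
* noise-ceiling-normalized explained variance (NNEV) — the share of the
  *explainable* variance a prediction accounts for.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .response_store import ResponseSet, TrialBetas

__all__ = [
    "EncodingModel",
    "VoxelNoiseProfile",
    "EncodingEvaluation",
    "compute_ncsnr",
    "noise_ceiling",
    "evaluate_encoding",
    "noise_comparison",
]

logger = logging.getLogger(__name__)


@runtime_checkable
class EncodingModel(Protocol):
    """Deterministic mapping from a stimulus batch to voxel responses.

    ``predict`` takes either a stack of pixel images
    ``(stimuli, H, W, 3) uint8`` or precomputed feature vectors and returns
    a ``(stimuli, voxel_count)`` array in z-units.  The same input must
    always yield the same output.
    """

    area: str
    participant: str
    voxel_count: int

    def predict(self, stimuli) -> np.ndarray: ...


@dataclass
class VoxelNoiseProfile:
    """Per-voxel signal/noise decomposition estimated from trial repeats."""

    ncsnr: np.ndarray
    sigma_noise: np.ndarray
    sigma_signal: np.ndarray
    per_image_beta_variance: np.ndarray | None = None

    def nc_of_n(self, n: int) -> np.ndarray:
        """Noise ceiling (percent) per voxel for n averaged trials."""
        return noise_ceiling(self.ncsnr, n)


@dataclass
class EncodingEvaluation:
    """Per-voxel evaluation of one prediction against one target."""

    r: np.ndarray
    r2: np.ndarray
    nnev: np.ndarray
    area_mean_nnev: float

    def as_frame(self, nc: np.ndarray | None = None) -> pd.DataFrame:
        data = {"r": self.r, "r2": self.r2, "nnev": self.nnev}
        if nc is not None:
            data["nc"] = nc
        return pd.DataFrame(data)


def compute_ncsnr(trials: TrialBetas) -> VoxelNoiseProfile:
    """Estimate per-voxel NCSNR from repeated presentations.

    Expects z-scored betas (overall per-voxel variance ~ 1) where every
    image has at least 2 repeats.  The noise standard deviation is the
    square root of the across-repeat variance (unbiased, n-1 estimator)
    averaged over images; the signal standard deviation follows from the
    unit total variance by positive half-wave rectification:
    sigma_signal = sqrt(max(1 - sigma_noise^2, 0)).  Voxels with zero
    noise get NCSNR = +inf.
    """
    overall_var = trials.betas.var(axis=0, ddof=0)
    if np.any(np.abs(overall_var - 1.0) > 0.2):
        warnings.warn(
            "per-voxel variance deviates from 1; betas may not be z-scored",
            stacklevel=2,
        )
    image_ids = pd.unique(trials.image_of_trial)
    per_image_var = np.empty((len(image_ids), trials.n_voxels))
    for i, iid in enumerate(image_ids):
        block = trials.betas[trials.image_of_trial == iid]
        if block.shape[0] < 2:
            raise ValueError(f"image {iid!r} has fewer than 2 repeats")
        per_image_var[i] = block.var(axis=0, ddof=1)
    noise_var = per_image_var.mean(axis=0)
    sigma_noise = np.sqrt(noise_var)
    sigma_signal = np.sqrt(np.clip(1.0 - noise_var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        ncsnr = np.where(
            sigma_noise == 0, np.inf, sigma_signal / np.where(sigma_noise == 0, 1, sigma_noise)
        )
    return VoxelNoiseProfile(
        ncsnr=ncsnr,
        sigma_noise=sigma_noise,
        sigma_signal=sigma_signal,
        per_image_beta_variance=per_image_var,
    )


def noise_ceiling(ncsnr, n: int):
    """Noise ceiling in percent for ``n`` averaged trials.

    NC = 100 * NCSNR^2 / (NCSNR^2 + 1/n); NC(0) = 0 and NC(+inf) = 100.
    Accepts scalars or arrays.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ncsnr_arr = np.asarray(ncsnr, dtype=float)
    if np.any(ncsnr_arr < 0):
        raise ValueError("NCSNR must be non-negative")
    with np.errstate(invalid="ignore"):
        nc = np.where(
            np.isinf(ncsnr_arr),
            100.0,
            100.0 * ncsnr_arr**2 / (ncsnr_arr**2 + 1.0 / n),
        )
    if np.isscalar(ncsnr) or np.ndim(ncsnr) == 0:
        return float(nc)
    return nc


def _columnwise_pearson(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson r per column; zero-variance columns yield r = 0."""
    pc = pred - pred.mean(axis=0)
    tc = target - target.mean(axis=0)
    pn = np.sqrt((pc**2).sum(axis=0))
    tn = np.sqrt((tc**2).sum(axis=0))
    bad = (pn == 0) | (tn == 0)
    if np.any(bad):
        logger.info("%d zero-variance columns; their r set to 0", int(bad.sum()))
    denom = np.where(bad, 1.0, pn * tn)
    r = (pc * tc).sum(axis=0) / denom
    return np.where(bad, 0.0, r)


def evaluate_encoding(
    pred: np.ndarray,
    target: np.ndarray,
    noise: VoxelNoiseProfile,
    n: int,
) -> EncodingEvaluation:
    """Score a prediction with noise-ceiling-normalized explained variance.

    Per voxel: Pearson r across stimuli, negative r set to zero, squared
    into r^2, then divided by the fraction of explainable variance NC(n)/100
    and expressed in percent, capped at 100.  Voxels whose noise ceiling is
    zero have undefined NNEV and contribute 0.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("prediction and target shapes differ")
    if pred.shape[0] < 3:
        raise ValueError("need at least 3 stimuli to correlate")
    r = _columnwise_pearson(pred, target)
    r2 = np.maximum(r, 0.0) ** 2
    nc = noise.nc_of_n(n)
    nc_frac = np.asarray(nc, dtype=float) / 100.0
    with np.errstate(divide="ignore", invalid="ignore"):
        nnev = np.where(nc_frac > 0, 100.0 * r2 / np.where(nc_frac > 0, nc_frac, 1), 0.0)
    nnev = np.minimum(nnev, 100.0)
    return EncodingEvaluation(
        r=r, r2=r2, nnev=nnev, area_mean_nnev=float(nnev.mean())
    )


def noise_comparison(
    trials: TrialBetas,
    insilico: ResponseSet,
    noise: VoxelNoiseProfile,
) -> pd.Series:
    """Compare three predictors of single left-out trials.

    Requires exactly 3 repeats per image.  Each single trial is explained,
    with the n=1 noise ceiling, by

    a. ``single_trial`` — one of the two remaining trials (6 ordered
       target/predictor pairs, averaged),
    b. ``trial_average`` — the mean of the two remaining trials (3
       predictions, averaged),
    c. ``insilico`` — the model-generated responses (3 predictions,
       averaged).

    Returns the mean NNEV per predictor.  Model-generated responses beating
    single-trial predictors indicates they are less noise-afflicted than
    measured ones.
    """
    image_ids = pd.unique(trials.image_of_trial)
    stacked = np.empty((3, len(image_ids), trials.n_voxels))
    for i, iid in enumerate(image_ids):
        block = trials.betas[trials.image_of_trial == iid]
        if block.shape[0] != 3:
            raise ValueError(
                f"image {iid!r} has {block.shape[0]} repeats; exactly 3 required"
            )
        stacked[:, i, :] = block
    model = insilico.rows_for(image_ids)

    def mean_nnev(pred, target):
        return evaluate_encoding(pred, target, noise, n=1).area_mean_nnev

    single = []
    for t in range(3):
        for p in range(3):
            if p != t:
                single.append(mean_nnev(stacked[p], stacked[t]))
    pair_avg = []
    silico = []
    for t in range(3):
        others = [p for p in range(3) if p != t]
        pair_avg.append(mean_nnev(stacked[others].mean(axis=0), stacked[t]))
        silico.append(mean_nnev(model, stacked[t]))
    return pd.Series(
        {
            "single_trial": float(np.mean(single)),
            "trial_average": float(np.mean(pair_avg)),
            "insilico": float(np.mean(silico)),
        },
        name="mean_nnev",
    )
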