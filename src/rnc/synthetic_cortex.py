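"""Synthetic multi-area cortex, toy image-computable encoders, toy generator.

These simulators make the whole control pipeline testable without any
neuroimaging download:

* :func:`simulate_hierarchy` plants a known representational structure
  across a chain (or grouped set) of areas: the content shared between two
  areas decays geometrically with their hierarchy distance, emulating the
  stepwise increase of unique representational content along the visual
  hierarchy, with per-voxel noise heterogeneity and multiple participants.
* :func:`simulate_trials` adds repeat-level noise so that NCSNR and
  noise-ceiling estimators can be checked against planted values.
* :func:`toy_image_encoders` returns two deterministic image-computable
  models: a "freq" area responding to local gradient energy (an early,
  spatial-frequency-tuned caricature) and a "blob" area responding to
  discrete object-like shapes (a mid-level caricature).
* :func:`toy_generator` is a small parametric image generator whose latent
  space splits into blob controls and sinusoid controls.

All simulators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .response_store import ResponseSet, TrialBetas, zscore_per_session

__all__ = [
    "AreaSpec",
    "SyntheticCortexConfig",
    "SyntheticGroundTruth",
    "simulate_hierarchy",
    "simulate_trials",
    "ToyEncoder",
    "toy_image_encoders",
    "ToyGenerator",
    "toy_generator",
]


@dataclass(frozen=True)
class AreaSpec:
    """One simulated area: name, integer hierarchy position, optional group."""

    name: str
    position: int
    group: str | None = None


def chain_areas(names=("V1", "V2", "V3", "V4")) -> tuple[AreaSpec, ...]:
    """A stepwise hierarchy: consecutive positions 0..n-1."""
    return tuple(AreaSpec(n, i) for i, n in enumerate(names))


def grouped_areas(
    groups={"animate": ("EBA", "FFA"), "scene": ("PPA", "RSC")},
    within_step: int = 1,
    between_step: int = 4,
) -> tuple[AreaSpec, ...]:
    """Two categorical groups: small within-group, large between-group distance."""
    out = []
    base = 0
    for gname, members in groups.items():
        for j, m in enumerate(members):
            out.append(AreaSpec(m, base + j * within_step, gname))
        base += between_step + (len(members) - 1) * within_step
    return tuple(out)


@dataclass
class SyntheticCortexConfig:
    """Study conditions for the synthetic cortex.

    Defaults emulate the real-data setting the analyses assume: 8
    participants, 4 areas in a stepwise hierarchy, 3 trial repeats for
    noise-ceiling work, and shared representational content that decays by
    ``share_decay`` per hierarchy step.
    """

    n_participants: int = 8
    areas: tuple[AreaSpec, ...] = field(default_factory=chain_areas)
    voxels_per_area: int = 80
    n_images: int = 2000
    latent_dim: int = 20
    share_decay: float = 0.35
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.share_decay <= 1.0):
            raise ValueError("share_decay must lie in [0, 1]")
        for name, v in [
            ("n_participants", self.n_participants),
            ("voxels_per_area", self.voxels_per_area),
            ("n_images", self.n_images),
            ("latent_dim", self.latent_dim),
        ]:
            if v < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SyntheticGroundTruth:
    """What was planted: loadings, latents, planted pairwise correlations."""

    loadings: dict
    image_latents: dict
    univariate_factors: dict
    planted_profile_correlation: pd.DataFrame
    image_ids: np.ndarray


def _ar1_chain(positions, n, dim, rho, rng):
    """Factors per hierarchy position with corr(x_p, x_q) = rho^|p-q|."""
    factors = {}
    prev_pos = None
    for pos in sorted(positions):
        draw = rng.standard_normal((n, dim))
        if prev_pos is None:
            factors[pos] = draw
        else:
            gap = pos - prev_pos
            w = rho**gap
            factors[pos] = w * factors[prev_pos] + np.sqrt(1.0 - w**2) * draw
        prev_pos = pos
    return factors


def simulate_hierarchy(cfg: SyntheticCortexConfig):
    """Simulate z-scored responses for every (participant, area).

    Each area's response to image i at voxel v decomposes into a scalar
    univariate factor (identical for all of the area's voxels, hence
    carrying the univariate profile), a voxel-patterned component (mean
    removed across voxels, hence carrying the representational geometry
    but not the profile) and participant-specific Gaussian voxel noise.
    Both factors follow a first-order autoregressive chain over hierarchy
    positions with per-step correlation 1 - share_decay, so the planted
    cross-area profile correlation is (1 - share_decay)^distance.

    Returns ``(response_sets, ground_truth)`` where ``response_sets`` maps
    ``(participant, area_name) -> ResponseSet``.
    """
    rng = np.random.default_rng(cfg.seed)
    rho = 1.0 - cfg.share_decay
    positions = sorted({a.position for a in cfg.areas})
    uni = _ar1_chain(positions, cfg.n_images, 1, rho, rng)
    lat = _ar1_chain(positions, cfg.n_images, cfg.latent_dim, rho, rng)
    image_ids = np.array([f"img{i:05d}" for i in range(cfg.n_images)], dtype=object)

    loadings = {}
    signals = {}
    meta = {}
    for area in cfg.areas:
        W = rng.standard_normal((cfg.latent_dim, cfg.voxels_per_area))
        W /= np.sqrt(cfg.latent_dim)
        loadings[area.name] = W
        pattern = lat[area.position] @ W
        pattern -= pattern.mean(axis=1, keepdims=True)  # keep profile = factor
        signal = uni[area.position] + pattern
        signals[area.name] = signal
        # heterogeneous per-voxel noise scale -> NCSNR heterogeneity
        noise_scale = cfg.noise_sd * rng.uniform(0.5, 1.5, cfg.voxels_per_area)
        signal_sd = signal.std(axis=0, ddof=0)
        with np.errstate(divide="ignore"):
            ncsnr = np.where(
                noise_scale == 0, np.inf, signal_sd / np.where(noise_scale == 0, 1, noise_scale)
            )
        vf = np.where(np.arange(cfg.voxels_per_area) % 2 == 0, "lower", "upper")
        meta[area.name] = (noise_scale, ncsnr, vf)

    response_sets = {}
    for p in range(cfg.n_participants):
        pid = f"sub{p + 1:02d}"
        for area in cfg.areas:
            noise_scale, ncsnr, vf = meta[area.name]
            resp = signals[area.name] + noise_scale * rng.standard_normal(
                (cfg.n_images, cfg.voxels_per_area)
            )
            resp = (resp - resp.mean(axis=0)) / resp.std(axis=0, ddof=0)
            response_sets[(pid, area.name)] = ResponseSet(
                participant=pid,
                area=area.name,
                responses=resp,
                image_ids=image_ids,
                voxel_meta=pd.DataFrame({"ncsnr": ncsnr, "visual_field": vf}),
            )

    names = [a.name for a in cfg.areas]
    planted = pd.DataFrame(
        [[rho ** abs(a.position - b.position) for b in cfg.areas] for a in cfg.areas],
        index=names,
        columns=names,
    )
    truth = SyntheticGroundTruth(
        loadings=loadings,
        image_latents={p: lat[p] for p in positions},
        univariate_factors={p: uni[p][:, 0] for p in positions},
        planted_profile_correlation=planted,
        image_ids=image_ids,
    )
    return response_sets, truth


def simulate_trials(
    rs: ResponseSet, repeats: int, noise_sd: float, seed: int, n_sessions: int = 1
) -> TrialBetas:
    """Replicate each image ``repeats`` times with additive Gaussian noise.

    The z-scored image-level responses act as the signal (unit sd per
    voxel), so the planted NCSNR is 1/noise_sd.  Trials are repeat-major
    (all images once, then again) and are session-z-scored before return.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    rng = np.random.default_rng(seed)
    blocks, images, sessions = [], [], []
    per_session = int(np.ceil(repeats / n_sessions))
    for rep in range(repeats):
        blocks.append(
            rs.responses + noise_sd * rng.standard_normal(rs.responses.shape)
        )
        images.append(rs.image_ids)
        sessions.append(np.full(rs.n_images, f"ses{rep // per_session + 1:02d}"))
    trials = TrialBetas(
        participant=rs.participant,
        area=rs.area,
        betas=np.vstack(blocks),
        image_of_trial=np.concatenate(images),
        session_of_trial=np.concatenate(sessions),
    )
    return zscore_per_session(trials)


# ---------------------------------------------------------------------------
# Toy image-computable encoders
# ---------------------------------------------------------------------------

def _check_images(images) -> np.ndarray:
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3 or arr.dtype != np.uint8:
        raise ValueError("expected uint8 images of shape (H, W, 3) or (N, H, W, 3)")
    return arr


def _grayscale(images: np.ndarray) -> np.ndarray:
    return images.astype(float).mean(axis=-1)


class ToyEncoder:
    """Deterministic image-computable encoder over a grid of subwindows.

    Each "voxel" is one subwindow of the image; its raw score is either the
    mean absolute pixel-gradient magnitude ("freq") or the count of
    connected components with area within bounds after grayscale
    thresholding ("blob").  Raw scores are standardized against a frozen
    reference image set so outputs are in z-like units and a batch of
    typical generator outputs sits near zero.
    """

    def __init__(
        self,
        kind: str,
        image_size: int = 64,
        grid: int = 4,
        threshold: float = 40.0,
        area_bounds: tuple[int, int] = (5, 200),
        participant: str = "toy",
    ):
        if kind not in ("freq", "blob"):
            raise ValueError("kind must be 'freq' or 'blob'")
        self.kind = kind
        self.area = kind
        self.participant = participant
        self.image_size = image_size
        self.grid = grid
        self.threshold = threshold
        self.area_bounds = area_bounds
        self.voxel_count = grid * grid
        self._ref_mean = np.zeros(self.voxel_count)
        self._ref_sd = np.ones(self.voxel_count)

    def _raw_scores(self, images: np.ndarray) -> np.ndarray:
        gray = _grayscale(images)
        n, h, w = gray.shape
        step_h, step_w = h // self.grid, w // self.grid
        scores = np.empty((n, self.voxel_count))
        if self.kind == "freq":
            # forward differences (zero-padded) so single-pixel alternation
            # registers, unlike central differences
            gx = np.zeros_like(gray)
            gy = np.zeros_like(gray)
            gx[:, :, :-1] = np.abs(np.diff(gray, axis=2))
            gy[:, :-1, :] = np.abs(np.diff(gray, axis=1))
            mag = np.sqrt(gx**2 + gy**2)
            for gi in range(self.grid):
                for gj in range(self.grid):
                    win = mag[:, gi * step_h : (gi + 1) * step_h,
                              gj * step_w : (gj + 1) * step_w]
                    scores[:, gi * self.grid + gj] = win.mean(axis=(1, 2))
        else:
            fg = np.abs(gray - 127.0) > self.threshold
            lo, hi = self.area_bounds
            for k in range(n):
                for gi in range(self.grid):
                    for gj in range(self.grid):
                        win = fg[k, gi * step_h : (gi + 1) * step_h,
                                 gj * step_w : (gj + 1) * step_w]
                        labels, n_comp = ndimage.label(win)
                        count = 0
                        if n_comp:
                            sizes = np.bincount(labels.ravel())[1:]
                            count = int(((sizes >= lo) & (sizes <= hi)).sum())
                        scores[k, gi * self.grid + gj] = count
        return scores

    def standardize_on(self, reference_images) -> "ToyEncoder":
        ref = self._raw_scores(_check_images(reference_images))
        self._ref_mean = ref.mean(axis=0)
        sd = ref.std(axis=0, ddof=0)
        self._ref_sd = np.where(sd == 0, 1.0, sd)
        return self

    def predict(self, stimuli) -> np.ndarray:
        raw = self._raw_scores(_check_images(stimuli))
        return (raw - self._ref_mean) / self._ref_sd


def toy_image_encoders(
    image_size: int = 64, grid: int = 4, reference_seed: int = 1234,
    n_reference: int = 256,
) -> tuple[ToyEncoder, ToyEncoder]:
    """Build the ("freq", "blob") encoder pair, standardized on a frozen
    reference set of generator outputs (deterministic given the defaults)."""
    gen = toy_generator(latent_dim=16, image_size=image_size)
    rng = np.random.default_rng(reference_seed)
    reference = gen.generate(rng.standard_normal((n_reference, gen.latent_dim)))
    freq = ToyEncoder("freq", image_size=image_size, grid=grid)
    blob = ToyEncoder("blob", image_size=image_size, grid=grid)
    freq.standardize_on(reference)
    blob.standardize_on(reference)
    return freq, blob


# ---------------------------------------------------------------------------
# Toy parametric image generator
# ---------------------------------------------------------------------------

class ToyGenerator:
    """Deterministic latent -> image map.

    The first half of the latent vector controls a grid of blob
    intensities and sizes; the second half controls an additive sinusoid's
    frequencies, contrast and phase.  A zero latent yields a uniform
    mid-gray image; outputs are clamped to [0, 255] uint8.
    """

    def __init__(self, latent_dim: int = 16, image_size: int = 64):
        if latent_dim < 8:
            raise ValueError("latent_dim must be >= 8")
        self.latent_dim = latent_dim
        self.image_size = image_size
        half = latent_dim // 2
        self._blob_grid = max(1, int(np.floor(np.sqrt(half))))

    def generate(self, latents) -> np.ndarray:
        lat = np.atleast_2d(np.asarray(latents, dtype=float))
        if lat.shape[1] != self.latent_dim:
            raise ValueError(
                f"latent length {lat.shape[1]} != latent_dim {self.latent_dim}"
            )
        s = self.image_size
        yy, xx = np.mgrid[0:s, 0:s].astype(float)
        half = self.latent_dim // 2
        g = self._blob_grid
        centers = (np.arange(g) + 0.5) * s / g
        out = np.empty((lat.shape[0], s, s, 3), dtype=np.uint8)
        for k, z in enumerate(lat):
            canvas = np.full((s, s), 127.0)
            blobs = z[: g * g]
            for b, val in enumerate(blobs):
                if val == 0:
                    continue
                cy, cx = centers[b // g], centers[b % g]
                radius = 3.0 + 2.5 * min(abs(val), 3.0)
                amp = 90.0 * np.tanh(val)
                mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
                canvas[mask] += amp
            zh = z[half:]
            fx, fy = 0.8 * abs(zh[0]), 0.8 * abs(zh[1])
            contrast = 60.0 * np.tanh(zh[2])
            phase = zh[3]
            if contrast != 0.0 and (fx or fy):
                canvas += contrast * np.sin(fx * xx + fy * yy + phase)
            out[k] = np.clip(canvas, 0, 255).astype(np.uint8)[..., None]
        return out


def toy_generator(latent_dim: int = 16, image_size: int = 64) -> ToyGenerator:
    return ToyGenerator(latent_dim=latent_dim, image_size=image_size)
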