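"""Generative univariate control: latent evolution with a complexity goal.

A population of generator latents is evolved against two encoding models
under a two-phase objective.  Until both areas' univariate responses pass
their thresholds (baseline plus/minus a 0.6 z-unit margin), latents are
ranked by the condition-signed sum or difference of the two responses
plus a large constant penalty; once an image passes both thresholds, its
score becomes the byte size of its losslessly PNG-compressed image, so
evolution then minimizes image complexity while the constant penalty
keeps every threshold-passing image ranked ahead of every failing one.
Selection is elitist with softmax-probability parent sampling, biased
75/25 recombination and sparse additive Gaussian mutation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from PIL import Image

from .univariate import UniControlCondition

__all__ = [
    "Generator",
    "GenerativeConfig",
    "EvolutionTrace",
    "png_complexity",
    "global_score",
    "selection_probabilities",
    "make_next_generation",
    "evolve_controlling_image",
]


@runtime_checkable
class Generator(Protocol):
    """Deterministic latent-to-image map with uint8 output in [0, 255]."""

    latent_dim: int

    def generate(self, latents) -> np.ndarray: ...


@dataclass
class GenerativeConfig:
    """Evolution hyperparameters (population split, mixing, mutation)."""

    population: int = 1000
    n_elite: int = 250
    n_children: int = 750
    parent_mix: tuple = (0.75, 0.25)
    mutation_prob: float = 0.25
    mutation_sd: float = 0.75
    softmax_scale: float = 0.5
    penalty: float = 1e10
    generations: int = 500
    threshold_margin: float = 0.6
    condition: UniControlCondition = field(
        default_factory=lambda: UniControlCondition("drive_both")
    )
    png_compress_level: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_elite + self.n_children != self.population:
            raise ValueError("n_elite + n_children must equal population")
        if not np.isclose(sum(self.parent_mix), 1.0):
            raise ValueError("parent_mix fractions must sum to 1")
        for name, p in [("mutation_prob", self.mutation_prob)]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GenerationRecord:
    best_latent: np.ndarray
    best_image: np.ndarray
    resp_a: float
    resp_b: float
    png_bytes: int
    global_score: float
    passes: bool


@dataclass
class EvolutionTrace:
    """Per-generation best records plus the phase-switch generation."""

    records: list
    phase_switch: int | None

    @property
    def best_scores(self) -> np.ndarray:
        return np.asarray([r.global_score for r in self.records])

    @property
    def png_sizes(self) -> np.ndarray:
        return np.asarray([r.png_bytes for r in self.records])

    @property
    def final(self) -> GenerationRecord:
        return self.records[-1]


def png_complexity(image: np.ndarray, compress_level: int = 9) -> int:
    """Byte size of the lossless PNG encoding at a fixed compression level."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3 or arr.dtype != np.uint8:
        raise ValueError("expected a uint8 image of shape (H, W, 3)")
    buf = io.BytesIO()
    Image.fromarray(arr).save(buf, format="PNG", compress_level=compress_level)
    return buf.getbuffer().nbytes


def _thresholds(condition: UniControlCondition, base_a, base_b, margin):
    """Per-area (direction, level): True = must exceed, False = must be below."""
    return (
        (condition.drive_a, base_a + (margin if condition.drive_a else -margin)),
        (condition.drive_b, base_b + (margin if condition.drive_b else -margin)),
    )


def _objective_value(condition: UniControlCondition, resp_a, resp_b):
    """Condition-signed scalar, lower = better (closer to the control goal)."""
    resp_a = np.asarray(resp_a, dtype=float)
    resp_b = np.asarray(resp_b, dtype=float)
    if condition.label == "drive_both":
        return -(resp_a + resp_b)
    if condition.label == "suppress_both":
        return resp_a + resp_b
    if condition.label == "drive_A_suppress_B":
        return -(resp_a - resp_b)
    return resp_a - resp_b


def _passes(thresholds, resp_a, resp_b):
    (up_a, lvl_a), (up_b, lvl_b) = thresholds
    ok_a = resp_a > lvl_a if up_a else resp_a < lvl_a
    ok_b = resp_b > lvl_b if up_b else resp_b < lvl_b
    return np.logical_and(ok_a, ok_b)


def global_score(
    resp_a,
    resp_b,
    objective_value,
    thresholds,
    png_bytes,
    penalty: float = 1e10,
):
    """Two-phase score, lower = better.

    Failing either threshold scores ``objective_value + penalty``;
    passing both scores the PNG byte count.  Because the penalty exceeds
    any PNG size, passing latents always outrank failing ones, and among
    failing latents the condition-signed objective drives responses
    toward threshold.
    """
    passes = _passes(thresholds, np.asarray(resp_a, float), np.asarray(resp_b, float))
    return np.where(
        passes,
        np.asarray(png_bytes, dtype=float),
        np.asarray(objective_value, dtype=float) + penalty,
    )


def selection_probabilities(scores, softmax_scale: float = 0.5) -> np.ndarray:
    """Turn global scores into parent-selection probabilities.

    Fitness is the negated score (lower score = better), z-scored, scaled
    and passed through a softmax; all-equal scores give the uniform
    distribution.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    fitness = -scores
    sd = fitness.std(ddof=0)
    if sd == 0:
        return np.full(scores.size, 1.0 / scores.size)
    z = (fitness - fitness.mean()) / sd * softmax_scale
    e = np.exp(z - z.max())
    return e / e.sum()


def make_next_generation(
    latents: np.ndarray,
    probabilities: np.ndarray,
    cfg: GenerativeConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Elitist recombination step.

    The ``n_elite`` highest-probability latents are copied untouched.
    Each of the ``n_children`` children takes each component from the
    higher-probability parent with probability ``parent_mix[0]`` (the two
    parents are sampled by selection probability), then every component
    is mutated with probability ``mutation_prob`` by adding
    Normal(0, mutation_sd^2) noise.
    """
    latents = np.asarray(latents, dtype=float)
    if latents.shape[0] != cfg.population:
        raise ValueError("latent count must equal cfg.population")
    order = np.argsort(-probabilities, kind="stable")
    elites = latents[order[: cfg.n_elite]]
    dim = latents.shape[1]
    parents = rng.choice(
        cfg.population, size=(cfg.n_children, 2), p=probabilities
    )
    pa, pb = parents[:, 0], parents[:, 1]
    # orient so "first" is the higher-probability parent
    swap = probabilities[pb] > probabilities[pa]
    pa, pb = np.where(swap, pb, pa), np.where(swap, pa, pb)
    take_first = rng.random((cfg.n_children, dim)) < cfg.parent_mix[0]
    children = np.where(take_first, latents[pa], latents[pb])
    mutate = rng.random((cfg.n_children, dim)) < cfg.mutation_prob
    children = children + mutate * rng.normal(
        0.0, cfg.mutation_sd, size=(cfg.n_children, dim)
    )
    return np.vstack([elites, children])


def _univariate_response(models, images) -> np.ndarray:
    """Mean response over voxels, averaged across the supplied models."""
    if not isinstance(models, (list, tuple)):
        models = [models]
    preds = [np.asarray(m.predict(images), dtype=float).mean(axis=1) for m in models]
    return np.mean(preds, axis=0)


def evolve_controlling_image(
    generator: Generator,
    model_a,
    model_b,
    baseline_a: float,
    baseline_b: float,
    cfg: GenerativeConfig,
) -> EvolutionTrace:
    """Evolve a single maximally simple image satisfying a control condition.

    ``model_a``/``model_b`` may be single encoding models or lists (their
    univariate predictions are averaged, mirroring pooling across
    participants).  Returns the full per-generation trace; the
    phase-switch generation is the first whose best latent passes both
    response thresholds.
    """
    rng = np.random.default_rng(cfg.seed)
    thresholds = _thresholds(
        cfg.condition, baseline_a, baseline_b, cfg.threshold_margin
    )
    latents = rng.standard_normal((cfg.population, generator.latent_dim))
    records: list[GenerationRecord] = []
    phase_switch = None
    for gen in range(cfg.generations):
        images = generator.generate(latents)
        resp_a = _univariate_response(model_a, images)
        resp_b = _univariate_response(model_b, images)
        png_bytes = np.asarray(
            [png_complexity(img, cfg.png_compress_level) for img in images]
        )
        objective = _objective_value(cfg.condition, resp_a, resp_b)
        scores = global_score(
            resp_a, resp_b, objective, thresholds, png_bytes, cfg.penalty
        )
        best = int(np.argmin(scores))
        passes = bool(_passes(thresholds, resp_a[best], resp_b[best]))
        if passes and phase_switch is None:
            phase_switch = gen
        records.append(
            GenerationRecord(
                best_latent=latents[best].copy(),
                best_image=images[best].copy(),
                resp_a=float(resp_a[best]),
                resp_b=float(resp_b[best]),
                png_bytes=int(png_bytes[best]),
                global_score=float(scores[best]),
                passes=passes,
            )
        )
        if gen < cfg.generations - 1:
            probs = selection_probabilities(scores, cfg.softmax_scale)
            latents = make_next_generation(latents, probs, cfg, rng)
    return EvolutionTrace(records=records, phase_switch=phase_switch)
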