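"""Univariate relational neural control.

Given two areas' univariate profiles (mean-over-voxels response per
image), these routines find images that jointly control both areas:
driving or suppressing both (alignment), or driving one while suppressing
the other (disentanglement).  Control is always assessed against a
baseline — the mean response of the random image batch whose score lies
closest to the centre of a large random-batch null distribution — and
generalization is checked with participant-wise leave-one-out
cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .response_store import ResponseSet, UnivariateProfile

__all__ = [
    "CONDITIONS",
    "UniControlCondition",
    "UniNullDistribution",
    "ControlSolution",
    "build_univariate_null",
    "select_univariate_controls",
    "crossval_univariate",
    "profile_correlation",
    "aggregate_by_pair_group",
    "stepwise_distance_grouping",
    "within_between_grouping",
    "subset_contrast",
]

CONDITIONS = (
    "drive_both",
    "suppress_both",
    "drive_A_suppress_B",
    "drive_B_suppress_A",
)


@dataclass(frozen=True)
class UniControlCondition:
    """One univariate control condition with its baseline margin (z-units)."""

    label: str
    margin: float = 0.04

    def __post_init__(self) -> None:
        if self.label not in CONDITIONS:
            raise ValueError(f"unknown condition {self.label!r}")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")

    @property
    def drive_a(self) -> bool:
        return self.label in ("drive_both", "drive_A_suppress_B")

    @property
    def drive_b(self) -> bool:
        return self.label in ("drive_both", "drive_B_suppress_A")

    @property
    def aligning(self) -> bool:
        return self.label in ("drive_both", "suppress_both")


@dataclass
class UniNullDistribution:
    """Null distribution of random-batch mean responses for one area."""

    area: str
    batch_size: int
    sample_scores: np.ndarray
    baseline_image_ids: np.ndarray
    baseline_score: float

    @property
    def null_mean(self) -> float:
        return float(self.sample_scores.mean())


@dataclass
class ControlSolution:
    """Selected controlling images for one condition (optionally one fold)."""

    condition: UniControlCondition
    image_ids: np.ndarray
    selection_scores: np.ndarray
    eval: dict = field(default_factory=dict)
    fold: str = "pooled"
    complete: bool = True

    @property
    def n_selected(self) -> int:
        return len(self.image_ids)


def _sample_batches(n_images: int, batch_size: int, n_samples: int, seed: int,
                    chunk: int = 4096) -> np.ndarray:
    """(n_samples, batch_size) index array, batches drawn without
    replacement within batch, vectorized via random-key argpartition."""
    rng = np.random.default_rng(seed)
    out = np.empty((n_samples, batch_size), dtype=np.intp)
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        keys = rng.random((m, n_images))
        out[done : done + m] = np.argpartition(keys, batch_size - 1, axis=1)[
            :, :batch_size
        ]
        done += m
    return out


def build_univariate_null(
    profile: UnivariateProfile,
    batch_size: int = 25,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> UniNullDistribution:
    """Sample random image batches and score each by its mean response.

    The baseline batch is the sampled batch whose mean response lies
    closest to the null-distribution mean (ties broken by sample order).
    """
    n_images = len(profile.values)
    if batch_size > n_images:
        raise ValueError("batch_size cannot exceed the number of images")
    idx = _sample_batches(n_images, batch_size, n_samples, seed)
    scores = profile.values[idx].mean(axis=1)
    best = int(np.argmin(np.abs(scores - scores.mean())))
    return UniNullDistribution(
        area=profile.area,
        batch_size=batch_size,
        sample_scores=scores,
        baseline_image_ids=profile.image_ids[np.sort(idx[best])],
        baseline_score=float(scores[best]),
    )


def select_univariate_controls(
    prof_a: UnivariateProfile,
    prof_b: UnivariateProfile,
    base_a: float,
    base_b: float,
    condition: UniControlCondition,
    n_select: int = 25,
) -> ControlSolution:
    """Margin-filter then rank images by the sum or difference score.

    A driven area requires value > baseline + margin; a suppressed area
    requires value < baseline - margin.  Candidates are ranked by the sum
    of the two profiles for aligning conditions (descending for
    drive_both, ascending for suppress_both) or by the difference A - B
    for disentangling conditions (descending when A is driven).  Ties are
    broken by image id.  If fewer than ``n_select`` images qualify, the
    solution is returned incomplete (``complete=False``) rather than
    raising.
    """
    if not np.array_equal(prof_a.image_ids, prof_b.image_ids):
        raise ValueError("profiles must be indexed by identical image sets")
    a, b = prof_a.values, prof_b.values
    m = condition.margin
    ok_a = a > base_a + m if condition.drive_a else a < base_a - m
    ok_b = b > base_b + m if condition.drive_b else b < base_b - m
    candidates = np.flatnonzero(ok_a & ok_b)
    score = a + b if condition.aligning else a - b
    descending = condition.label in ("drive_both", "drive_A_suppress_B")
    key = -score if descending else score
    order = candidates[
        np.lexsort((prof_a.image_ids[candidates], key[candidates]))
    ]
    picked = order[:n_select]
    return ControlSolution(
        condition=condition,
        image_ids=prof_a.image_ids[picked],
        selection_scores=score[picked],
        complete=len(picked) == n_select,
    )


def _mean_profile(profiles: list[UnivariateProfile]) -> UnivariateProfile:
    ids = profiles[0].image_ids
    for p in profiles[1:]:
        if not np.array_equal(p.image_ids, ids):
            raise ValueError("profiles must share the same image set and order")
    return UnivariateProfile(
        participant="average",
        area=profiles[0].area,
        values=np.mean([p.values for p in profiles], axis=0),
        image_ids=ids,
    )


def crossval_univariate(
    profiles_a: list[UnivariateProfile],
    profiles_b: list[UnivariateProfile],
    condition: UniControlCondition,
    n_select: int = 25,
    batch_size: int = 25,
    n_null_samples: int = 100_000,
    seed: int = 0,
) -> list[ControlSolution]:
    """Participant-wise leave-one-out cross-validation of the selection.

    For each fold, the baseline null and the selection are computed on the
    profiles averaged over the training participants; the held-out
    participant's mean response over the selected images (and over the
    baseline images) evaluates the solution.  Returns one solution per
    participant, with ``eval`` holding the held-out responses and
    baselines for both areas.
    """
    n = len(profiles_a)
    if n < 2 or len(profiles_b) != n:
        raise ValueError("need >= 2 participants with matching area profiles")
    folds = []
    for held in range(n):
        train = [i for i in range(n) if i != held]
        avg_a = _mean_profile([profiles_a[i] for i in train])
        avg_b = _mean_profile([profiles_b[i] for i in train])
        null_a = build_univariate_null(avg_a, batch_size, n_null_samples, seed)
        null_b = build_univariate_null(avg_b, batch_size, n_null_samples, seed + 1)
        sol = select_univariate_controls(
            avg_a, avg_b, null_a.baseline_score, null_b.baseline_score,
            condition, n_select,
        )
        sol.fold = profiles_a[held].participant
        held_a = profiles_a[held].as_series()
        held_b = profiles_b[held].as_series()
        sol.eval = {
            "A": float(held_a.loc[sol.image_ids].mean()) if sol.n_selected else np.nan,
            "B": float(held_b.loc[sol.image_ids].mean()) if sol.n_selected else np.nan,
            "baseline_A": float(held_a.loc[null_a.baseline_image_ids].mean()),
            "baseline_B": float(held_b.loc[null_b.baseline_image_ids].mean()),
            "baseline_image_ids_A": null_a.baseline_image_ids,
            "baseline_image_ids_B": null_b.baseline_image_ids,
        }
        folds.append(sol)
    return folds


def profile_correlation(prof_a: UnivariateProfile, prof_b: UnivariateProfile) -> float:
    """Pearson correlation of two areas' profiles over shared images."""
    sa, sb = prof_a.as_series(), prof_b.as_series()
    shared = sa.index.intersection(sb.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared images")
    x, y = sa.loc[shared].to_numpy(), sb.loc[shared].to_numpy()
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance profile; correlation undefined", stacklevel=2)
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def stepwise_distance_grouping(ordered_areas) -> dict:
    """Map each area pair of an ordered chain to its stepwise distance."""
    pos = {a: i for i, a in enumerate(ordered_areas)}
    return {
        (x, y): abs(pos[x] - pos[y])
        for i, x in enumerate(ordered_areas)
        for y in list(ordered_areas)[i + 1 :]
    }


def within_between_grouping(groups: dict) -> dict:
    """Map each pair of grouped areas to 'within' or 'between'."""
    area_group = {a: g for g, members in groups.items() for a in members}
    areas = [a for members in groups.values() for a in members]
    return {
        (x, y): "within" if area_group[x] == area_group[y] else "between"
        for i, x in enumerate(areas)
        for y in areas[i + 1 :]
    }


def aggregate_by_pair_group(pair_stats: dict, grouping: dict) -> pd.Series:
    """Average a per-pair statistic within pair groups.

    ``grouping`` maps each (areaX, areaY) pair to a group label (e.g.
    stepwise distance, or within/between category).  Pairs are matched
    irrespective of order; an unmapped pair raises.
    """
    norm = {}
    for pair, g in grouping.items():
        norm[frozenset(pair)] = g
    rows = []
    for pair, stat in pair_stats.items():
        key = frozenset(pair)
        if key not in norm:
            raise ValueError(f"pair {pair!r} is not mapped to any group")
        rows.append((norm[key], stat))
    df = pd.DataFrame(rows, columns=["group", "stat"])
    return df.groupby("group", sort=True)["stat"].mean()


def subset_contrast(
    rs: ResponseSet,
    image_subset_labels,
    voxel_subset_labels,
    image_levels=None,
    voxel_levels=None,
) -> pd.DataFrame:
    """Mean response per (image subset, voxel subset) block.

    Supports contrasts such as sky/no-sky images crossed with voxels tuned
    to the lower versus upper visual field.  Levels default to those
    observed in the labels; explicitly requested levels with no members
    yield NaN cells with a warning.
    """
    img = np.asarray(image_subset_labels)
    vox = np.asarray(voxel_subset_labels)
    if len(img) != rs.n_images or len(vox) != rs.n_voxels:
        raise ValueError("label lengths must match image and voxel counts")
    img_levels = pd.unique(img) if image_levels is None else np.asarray(image_levels)
    vox_levels = pd.unique(vox) if voxel_levels is None else np.asarray(voxel_levels)
    out = pd.DataFrame(index=img_levels, columns=vox_levels, dtype=float)
    for il in img_levels:
        for vl in vox_levels:
            block = rs.responses[np.ix_(img == il, vox == vl)]
            if block.size == 0:
                warnings.warn(f"empty block ({il!r}, {vl!r})", stacklevel=2)
                out.loc[il, vl] = np.nan
            else:
                out.loc[il, vl] = float(block.mean())
    return out
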