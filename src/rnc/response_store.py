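"""Data model and I/O for fMRI-like response sets.

Two containers cover the pipeline: :class:`TrialBetas` holds trial-level
beta responses with image and session labels, and :class:`ResponseSet`
holds image-level responses (one row per image, typically repeat-averaged
and z-scored).  The preprocessing steps operating on them — per-session
z-scoring, repeat averaging, univariate reduction and NCSNR-based voxel
selection — mirror the standard treatment of single-trial beta estimates
in large-sample visual fMRI datasets.

All selections downstream of this module are expressed in image ids, never
positional indices; the image order inside a :class:`ResponseSet` is the
canonical order for indexing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TrialBetas",
    "ResponseSet",
    "UnivariateProfile",
    "DegenerateInputError",
    "EmptyAreaError",
    "StoreFormatError",
    "zscore_per_session",
    "average_repeats",
    "univariate_profile",
    "filter_voxels_by_ncsnr",
    "save_store",
    "load_store",
    "export_profile_csv",
]

SCHEMA_VERSION = "rnc-store-1"


class DegenerateInputError(ValueError):
    """A (voxel, session) slice has zero variance and cannot be z-scored."""


class EmptyAreaError(ValueError):
    """An operation requires at least one voxel but the area has none."""


class StoreFormatError(ValueError):
    """An on-disk container does not match the expected schema."""


def _as_str_array(values) -> np.ndarray:
    return np.asarray([str(v) for v in np.asarray(values).ravel()], dtype=object)


@dataclass
class TrialBetas:
    """Trial-level beta responses for one (participant, area).

    Parameters
    ----------
    betas
        ``(trials, voxels)`` array of beta estimates.
    image_of_trial
        Image id shown on each trial.
    session_of_trial
        Acquisition-session label of each trial; z-scoring is performed
        within session.
    """

    participant: str
    area: str
    betas: np.ndarray
    image_of_trial: np.ndarray
    session_of_trial: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 2:
            raise ValueError("betas must be a (trials, voxels) matrix")
        self.image_of_trial = _as_str_array(self.image_of_trial)
        self.session_of_trial = _as_str_array(self.session_of_trial)
        n = self.betas.shape[0]
        if len(self.image_of_trial) != n or len(self.session_of_trial) != n:
            raise ValueError("trial label lengths must match the beta row count")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def repeats_of(self, image_id: str) -> np.ndarray:
        """Rows of ``betas`` corresponding to one image's repeats."""
        return self.betas[self.image_of_trial == str(image_id)]


@dataclass
class ResponseSet:
    """Image-level responses ``(images, voxels)`` for one (participant, area).

    ``voxel_meta`` is a per-voxel table carrying at least an ``ncsnr``
    column (noise-ceiling signal-to-noise ratio, dimensionless, >= 0) and
    optionally a ``visual_field`` tag in {"lower", "upper", "none"}.
    """

    participant: str
    area: str
    responses: np.ndarray
    image_ids: np.ndarray
    voxel_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be an (images, voxels) matrix")
        self.image_ids = _as_str_array(self.image_ids)
        if len(self.image_ids) != self.responses.shape[0]:
            raise ValueError("image_ids length must match the response row count")
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ValueError("image_ids must be unique")
        if self.responses.size and not np.all(np.isfinite(self.responses)):
            raise ValueError("responses contain non-finite values")
        if self.voxel_meta is None:
            self.voxel_meta = pd.DataFrame(
                {"ncsnr": np.full(self.responses.shape[1], np.nan)}
            )
        self.voxel_meta = self.voxel_meta.reset_index(drop=True)
        if len(self.voxel_meta) != self.responses.shape[1]:
            raise ValueError("voxel_meta row count must match the voxel count")

    @property
    def n_images(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]

    def rows_for(self, image_ids) -> np.ndarray:
        """Response rows for the given image ids, in the given order."""
        index = {iid: i for i, iid in enumerate(self.image_ids)}
        try:
            pos = [index[str(i)] for i in image_ids]
        except KeyError as err:  # pragma: no cover - defensive
            raise KeyError(f"unknown image id {err.args[0]!r}") from None
        return self.responses[pos]


@dataclass
class UnivariateProfile:
    """Per-image mean-over-voxels response for one (participant, area)."""

    participant: str
    area: str
    values: np.ndarray
    image_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.image_ids = _as_str_array(self.image_ids)
        if len(self.values) != len(self.image_ids):
            raise ValueError("values and image_ids must have equal length")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("profile values contain non-finite entries")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.image_ids, name=self.area)


def zscore_per_session(trials: TrialBetas, ddof: int = 0) -> TrialBetas:
    """Z-score each voxel across all trials of each acquisition session.

    ``ddof=0`` (population standard deviation) is the default convention;
    pass ``ddof=1`` for the sample-sd convention.  Sessions are centred and
    scaled independently.

    Raises
    ------
    DegenerateInputError
        If any (voxel, session) slice has fewer than 2 trials or zero
        variance.
    """
    out = trials.betas.copy()
    for session in pd.unique(trials.session_of_trial):
        mask = trials.session_of_trial == session
        block = out[mask]
        if block.shape[0] < 2:
            raise DegenerateInputError(
                f"session {session!r} has fewer than 2 trials"
            )
        sd = block.std(axis=0, ddof=ddof)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise DegenerateInputError(
                f"voxel {bad[0]} has zero variance in session {session!r}"
            )
        out[mask] = (block - block.mean(axis=0)) / sd
    return dataclasses.replace(trials, betas=out)


def average_repeats(trials: TrialBetas) -> ResponseSet:
    """Average each image's trials into one image-level response row.

    The output row order is the first-appearance order of image ids in the
    trial sequence.
    """
    order = pd.unique(trials.image_of_trial)
    rows = np.empty((len(order), trials.n_voxels))
    for i, iid in enumerate(order):
        rows[i] = trials.betas[trials.image_of_trial == iid].mean(axis=0)
    return ResponseSet(
        participant=trials.participant,
        area=trials.area,
        responses=rows,
        image_ids=order,
    )


def univariate_profile(rs: ResponseSet) -> UnivariateProfile:
    """Reduce a response set to its univariate (mean-over-voxels) profile."""
    if rs.n_voxels == 0:
        raise EmptyAreaError(
            f"area {rs.area!r} of participant {rs.participant!r} has no voxels"
        )
    return UnivariateProfile(
        participant=rs.participant,
        area=rs.area,
        values=rs.responses.mean(axis=1),
        image_ids=rs.image_ids,
    )


def filter_voxels_by_ncsnr(rs: ResponseSet, threshold: float) -> ResponseSet:
    """Keep only voxels with NCSNR strictly above ``threshold``.

    Voxel order is preserved.  If no voxel survives, an error advises
    retrying with a lower threshold (the conventional fallback when an
    area has no voxels above the default cutoff).
    """
    ncsnr = np.asarray(rs.voxel_meta["ncsnr"], dtype=float)
    keep = np.flatnonzero(ncsnr > threshold)
    if keep.size == 0:
        raise EmptyAreaError(
            f"no voxel of area {rs.area!r} has NCSNR above {threshold}; "
            "consider lowering the threshold (e.g. 0.5 -> 0.4)"
        )
    return ResponseSet(
        participant=rs.participant,
        area=rs.area,
        responses=rs.responses[:, keep],
        image_ids=rs.image_ids,
        voxel_meta=rs.voxel_meta.iloc[keep].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def _group_name(participant: str, area: str) -> str:
    return f"{participant}/{area}"


def save_store(items, path) -> None:
    """Write ResponseSet/TrialBetas objects to one HDF5 container.

    Layout: one group per (participant, area) holding either image-level
    datasets (``responses``, ``image_ids``, ``ncsnr``, ``visual_field``) or
    trial-level datasets (``betas``, ``image_of_trial``,
    ``session_of_trial``).  A schema version attribute is required on read.
    """
    if isinstance(items, (ResponseSet, TrialBetas)):
        items = [items]
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for item in items:
            g = f.create_group(_group_name(item.participant, item.area))
            if isinstance(item, ResponseSet):
                g.attrs["kind"] = "response_set"
                g.create_dataset("responses", data=item.responses)
                g.create_dataset(
                    "image_ids", data=np.asarray(item.image_ids, dtype="S")
                )
                g.create_dataset(
                    "ncsnr", data=np.asarray(item.voxel_meta["ncsnr"], dtype=float)
                )
                vf = (
                    item.voxel_meta["visual_field"]
                    if "visual_field" in item.voxel_meta
                    else ["none"] * item.n_voxels
                )
                g.create_dataset("visual_field", data=np.asarray(vf, dtype="S"))
            elif isinstance(item, TrialBetas):
                g.attrs["kind"] = "trial_betas"
                g.create_dataset("betas", data=item.betas)
                g.create_dataset(
                    "image_of_trial", data=np.asarray(item.image_of_trial, dtype="S")
                )
                g.create_dataset(
                    "session_of_trial",
                    data=np.asarray(item.session_of_trial, dtype="S"),
                )
            else:  # pragma: no cover - defensive
                raise TypeError(f"cannot store object of type {type(item)!r}")


def _decode(arr) -> np.ndarray:
    return np.asarray([v.decode() if isinstance(v, bytes) else str(v) for v in arr],
                      dtype=object)


def load_store(path, participant: str | None = None, area: str | None = None):
    """Read a container written by :func:`save_store`.

    Returns a list of objects, or a single object when both ``participant``
    and ``area`` are given.
    """
    path = Path(path)
    out = []
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise StoreFormatError(
                f"expected schema {SCHEMA_VERSION!r}, found {version!r}"
            )
        for pname, pgroup in f.items():
            if participant is not None and pname != participant:
                continue
            for aname, g in pgroup.items():
                if area is not None and aname != area:
                    continue
                kind = g.attrs.get("kind")
                if kind == "response_set":
                    meta = pd.DataFrame(
                        {
                            "ncsnr": np.asarray(g["ncsnr"], dtype=float),
                            "visual_field": _decode(g["visual_field"][()]),
                        }
                    )
                    out.append(
                        ResponseSet(
                            participant=pname,
                            area=aname,
                            responses=np.asarray(g["responses"], dtype=float),
                            image_ids=_decode(g["image_ids"][()]),
                            voxel_meta=meta,
                        )
                    )
                elif kind == "trial_betas":
                    out.append(
                        TrialBetas(
                            participant=pname,
                            area=aname,
                            betas=np.asarray(g["betas"], dtype=float),
                            image_of_trial=_decode(g["image_of_trial"][()]),
                            session_of_trial=_decode(g["session_of_trial"][()]),
                        )
                    )
                else:
                    raise StoreFormatError(
                        f"group {pname}/{aname} has unknown kind {kind!r}"
                    )
    if participant is not None and area is not None:
        if not out:
            raise StoreFormatError(
                f"no group for participant {participant!r}, area {area!r}"
            )
        return out[0]
    return out


def export_profile_csv(profile: UnivariateProfile, path) -> None:
    """Write a univariate profile as CSV with columns image_id, value."""
    pd.DataFrame({"image_id": profile.image_ids, "value": profile.values}).to_csv(
        path, index=False
    )
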