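"""MDS embeddings of areas and proximity-to-opacity normalization.

Areas are embedded in two dimensions by metric MDS on the Euclidean
distances between their feature vectors — participant-averaged univariate
profiles, or the vectorized strictly-lower triangles of
participant-averaged RSMs.  Proximity in the embedding reflects
resemblance of representational content.  Because MDS solutions are
defined only up to rotation and reflection, all quantitative comparisons
use pairwise distances; the reported coordinates are canonically aligned
(first area at angle zero) purely for reproducible plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

__all__ = [
    "AreaEmbedding",
    "embed_univariate",
    "embed_rsm",
    "proximity_opacity",
]


@dataclass
class AreaEmbedding:
    areas: list
    coords: np.ndarray
    pairwise_input_distances: np.ndarray
    stress: float

    def embedded_distances(self) -> np.ndarray:
        return squareform(pdist(self.coords))


def _canonical_alignment(coords: np.ndarray) -> np.ndarray:
    """Rotate so the first area sits at angle 0 (distances unchanged)."""
    c = coords - coords.mean(axis=0)
    v = c[0]
    if np.allclose(v, 0):
        return c
    theta = np.arctan2(v[1], v[0])
    rot = np.array(
        [[np.cos(-theta), -np.sin(-theta)], [np.sin(-theta), np.cos(-theta)]]
    )
    return c @ rot.T


def _embed(features: np.ndarray, areas, seed: int) -> AreaEmbedding:
    if features.shape[0] < 3:
        raise ValueError("need at least 3 areas to embed")
    # metric MDS, Euclidean input dissimilarity, 10 restarts, 1000 max
    # iterations; the convergence eps follows the library's normalized-
    # stress scale
    mds = MDS(
        n_components=2,
        metric_mds=True,
        metric="euclidean",
        n_init=10,
        max_iter=1000,
        eps=1e-6,
        init="random",
        random_state=seed,
        normalized_stress=False,
    )
    with warnings.catch_warnings():
        # degenerate all-zero dissimilarities trip a harmless divide inside
        # the SMACOF convergence check
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        coords = mds.fit_transform(features)
    return AreaEmbedding(
        areas=list(areas),
        coords=_canonical_alignment(coords),
        pairwise_input_distances=squareform(pdist(features)),
        stress=float(mds.stress_),
    )


def embed_univariate(profiles: dict, seed: int = 0) -> AreaEmbedding:
    """Embed areas from participant-averaged univariate profiles.

    ``profiles`` maps area name to a 1-D response vector over a shared
    image set (all vectors must have equal length and a common image
    order).
    """
    areas = list(profiles)
    lengths = {len(np.ravel(v)) for v in profiles.values()}
    if len(lengths) != 1:
        raise ValueError("all areas must share the same image set")
    features = np.vstack([np.ravel(profiles[a]) for a in areas])
    return _embed(features, areas, seed)


def embed_rsm(rsms: dict, seed: int = 0) -> AreaEmbedding:
    """Embed areas from the strictly-lower triangles of their RSMs.

    ``rsms`` maps area name to an :class:`~rnc.multivariate.RSM` built on
    one identical image batch per area.
    """
    areas = list(rsms)
    first = rsms[areas[0]]
    for a in areas[1:]:
        if not np.array_equal(rsms[a].image_ids, first.image_ids):
            raise ValueError("all RSMs must be built on the same batch")
    features = np.vstack([rsms[a].lower_triangle() for a in areas])
    return _embed(features, areas, seed)


def proximity_opacity(distances: np.ndarray) -> np.ndarray:
    """Rescale pairwise distances to opacities in [0.1, 1].

    The smallest pairwise distance maps to opacity 1.0 (closest areas
    drawn fully opaque) and the largest to 0.1, linearly in between;
    invariant to a common scaling of the distances.  The diagonal is set
    to 1.  All-equal distances give all-1 opacities with a warning.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distances must be a square matrix")
    if not np.allclose(d, d.T) or np.any(d < 0):
        raise ValueError("distances must be symmetric and non-negative")
    iu = np.triu_indices(d.shape[0], k=1)
    off = d[iu]
    dmin, dmax = off.min(), off.max()
    if dmax == dmin:
        warnings.warn("all pairwise distances equal; opacities set to 1.0",
                      stacklevel=2)
        out = np.ones_like(d)
        return out
    out = 1.0 - 0.9 * (d - dmin) / (dmax - dmin)
    np.fill_diagonal(out, 1.0)
    return out
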