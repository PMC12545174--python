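"""Multivariate relational neural control.

Voxel response patterns are compared between areas through
representational similarity matrices (RSMs): for a batch of images, the
image-by-image Pearson-correlation matrix of the voxel patterns.  The RSA
score between two areas is the Pearson correlation of their RSMs'
strictly-lower-triangle entries.  An elitist genetic search over image
batches then finds batches with maximal RSA (aligned geometries) or
minimal absolute RSA (disentangled geometries), compared against a
random-batch baseline and cross-validated across participants.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .response_store import ResponseSet
from .univariate import _sample_batches

__all__ = [
    "RSM",
    "BatchSearchConfig",
    "RsaResult",
    "MultiNullDistribution",
    "compute_rsm",
    "rsa_score",
    "build_multivariate_null",
    "search_controlling_batches",
    "crossval_multivariate",
]


@dataclass
class RSM:
    """Representational similarity matrix over one image batch."""

    image_ids: np.ndarray
    matrix: np.ndarray

    def lower_triangle(self) -> np.ndarray:
        s = self.matrix.shape[0]
        return self.matrix[np.tril_indices(s, k=-1)]


@dataclass(frozen=True)
class RsaResult:
    r: float


@dataclass
class MultiNullDistribution:
    """Null distribution of random-batch RSA scores for one area pair."""

    areas: tuple
    batch_size: int
    sample_scores: np.ndarray
    baseline_image_ids: np.ndarray
    baseline_score: float

    @property
    def null_mean(self) -> float:
        return float(self.sample_scores.mean())


@dataclass
class BatchSearchConfig:
    """Elitist genetic search over duplicate-free image batches.

    Per generation the ``n_elite`` best batches are retained untouched;
    each spawns one mutated copy per entry of ``mutation_counts`` (that
    many images replaced by fresh uniform draws from the pool); and
    ``n_random`` entirely new random batches are added, which must total
    ``population``.
    """

    population: int = 2400
    batch_size: int = 50
    n_elite: int = 200
    mutation_counts: tuple = (1, 5, 12, 25, 38)
    n_random: int = 1200
    generations: int = 2000
    objective: str = "align"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in ("align", "disentangle"):
            raise ValueError("objective must be 'align' or 'disentangle'")
        expected = self.n_elite * (1 + len(self.mutation_counts)) + self.n_random
        if expected != self.population:
            raise ValueError(
                f"n_elite*(1+len(mutation_counts)) + n_random = {expected} "
                f"!= population = {self.population}"
            )
        if any(m >= self.batch_size for m in self.mutation_counts):
            raise ValueError("mutation counts must be smaller than batch_size")


def _normalized_patterns(rs: ResponseSet) -> np.ndarray:
    """Row-centred, row-normalized patterns: RSM = P @ P.T."""
    if rs.n_voxels < 2:
        raise ValueError("need at least 2 voxels for pattern correlations")
    p = rs.responses - rs.responses.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(p, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(
            f"image {rs.image_ids[bad[0]]!r} has a zero-variance voxel pattern"
        )
    return p / norms[:, None]


def compute_rsm(rs: ResponseSet, batch) -> RSM:
    """Image-by-image Pearson-correlation matrix of a batch's patterns."""
    batch = np.asarray([str(b) for b in batch], dtype=object)
    if len(set(batch)) != len(batch):
        raise ValueError("batches must be duplicate-free")
    patterns = _normalized_patterns(rs)
    index = {iid: i for i, iid in enumerate(rs.image_ids)}
    rows = patterns[[index[b] for b in batch]]
    m = rows @ rows.T
    np.fill_diagonal(m, 1.0)
    return RSM(image_ids=batch, matrix=np.clip(m, -1.0, 1.0))


def rsa_score(rsm_a: RSM, rsm_b: RSM) -> RsaResult:
    """Pearson r between the two RSMs' strictly-lower-triangle entries."""
    if not np.array_equal(rsm_a.image_ids, rsm_b.image_ids):
        raise ValueError("RSMs must be built on identical batches")
    x, y = rsm_a.lower_triangle(), rsm_b.lower_triangle()
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant RSM triangle; RSA undefined", stacklevel=2)
        return RsaResult(r=float("nan"))
    x = x - x.mean()
    y = y - y.mean()
    return RsaResult(
        r=float(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)))
    )


def _batch_rsa_scores(pa, pb, idx: np.ndarray) -> np.ndarray:
    """Vectorized lower-triangle RSA for many batches.

    ``pa``/``pb`` are either single normalized pattern arrays or stacks
    ``(participants, images, voxels)`` whose per-participant RSMs are
    averaged entry-wise before correlation.
    """
    def tri_vectors(p):
        stack = p if p.ndim == 3 else p[None]
        s = idx.shape[1]
        ti, tj = np.tril_indices(s, k=-1)
        rsms = 0.0
        for part in stack:
            rows = part[idx]  # (batches, s, voxels)
            rsms = rsms + np.einsum("biv,bjv->bij", rows, rows)
        rsms = rsms / stack.shape[0]
        return rsms[:, ti, tj]

    xa, xb = tri_vectors(pa), tri_vectors(pb)
    xa = xa - xa.mean(axis=1, keepdims=True)
    xb = xb - xb.mean(axis=1, keepdims=True)
    num = (xa * xb).sum(axis=1)
    denom = np.linalg.norm(xa, axis=1) * np.linalg.norm(xb, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom == 0, np.nan, num / denom)


def build_multivariate_null(
    rs_a,
    rs_b,
    batch_size: int = 50,
    n_samples: int = 1_000_000,
    seed: int = 0,
    chunk: int = 2048,
) -> MultiNullDistribution:
    """Null distribution of RSA scores over random duplicate-free batches.

    ``rs_a``/``rs_b`` may be single :class:`ResponseSet` objects or lists
    of them (per-participant RSMs averaged entry-wise before scoring).
    The baseline batch is the sample whose RSA score lies closest to the
    null mean.
    """
    list_a = rs_a if isinstance(rs_a, (list, tuple)) else [rs_a]
    list_b = rs_b if isinstance(rs_b, (list, tuple)) else [rs_b]
    ids = list_a[0].image_ids
    for rs in list(list_a) + list(list_b):
        if not np.array_equal(rs.image_ids, ids):
            raise ValueError("areas must share the same image set")
    pa = np.stack([_normalized_patterns(rs) for rs in list_a])
    pb = np.stack([_normalized_patterns(rs) for rs in list_b])
    rs_a, rs_b = list_a[0], list_b[0]
    n_images = rs_a.n_images
    idx = _sample_batches(n_images, batch_size, n_samples, seed)
    scores = np.empty(n_samples)
    for start in range(0, n_samples, chunk):
        sl = slice(start, min(start + chunk, n_samples))
        scores[sl] = _batch_rsa_scores(pa, pb, idx[sl])
    best = int(np.nanargmin(np.abs(scores - np.nanmean(scores))))
    return MultiNullDistribution(
        areas=(rs_a.area, rs_b.area),
        batch_size=batch_size,
        sample_scores=scores,
        baseline_image_ids=rs_a.image_ids[np.sort(idx[best])],
        baseline_score=float(scores[best]),
    )


def _batch_hashes(idx: np.ndarray) -> np.ndarray:
    """Deterministic per-batch tie-break keys (order-insensitive)."""
    out = np.empty(idx.shape[0], dtype=np.uint64)
    for i, row in enumerate(np.sort(idx, axis=1)):
        h = hashlib.blake2b(row.tobytes(), digest_size=8).digest()
        out[i] = np.frombuffer(h, dtype=np.uint64)[0]
    return out


def _rank_key(scores: np.ndarray, objective: str) -> np.ndarray:
    # lower key = better
    if objective == "align":
        return np.where(np.isnan(scores), np.inf, -scores)
    return np.where(np.isnan(scores), np.inf, np.abs(scores))


def _mutate_batches(elite_idx: np.ndarray, counts, n_images: int, rng) -> np.ndarray:
    rows = []
    for m in counts:
        for batch in elite_idx:
            new = batch.copy()
            pos = rng.choice(len(batch), size=m, replace=False)
            keep = set(np.delete(new, pos).tolist())
            repl = []
            while len(repl) < m:
                cand = int(rng.integers(n_images))
                if cand not in keep and cand not in repl:
                    repl.append(cand)
            new[pos] = repl
            rows.append(new)
    return np.asarray(rows, dtype=np.intp)


def search_controlling_batches(
    rs_a,
    rs_b,
    cfg: BatchSearchConfig,
):
    """Genetic search for the batch that best aligns or disentangles two
    areas' representational geometries.

    ``rs_a``/``rs_b`` may be single :class:`ResponseSet` objects or lists
    of them (one per training participant), in which case per-participant
    RSMs are averaged entry-wise before scoring.  Returns ``(best_image_ids,
    best_score, trace)`` where ``trace`` is the per-generation best score;
    elitism makes the trace monotone (non-decreasing r for ``align``,
    non-increasing |r| for ``disentangle``).
    """
    list_a = rs_a if isinstance(rs_a, (list, tuple)) else [rs_a]
    list_b = rs_b if isinstance(rs_b, (list, tuple)) else [rs_b]
    ids = list_a[0].image_ids
    for rs in list(list_a) + list(list_b):
        if not np.array_equal(rs.image_ids, ids):
            raise ValueError("all response sets must share the same image set")
    pa = np.stack([_normalized_patterns(rs) for rs in list_a])
    pb = np.stack([_normalized_patterns(rs) for rs in list_b])
    n_images = len(ids)
    if n_images < cfg.batch_size:
        raise ValueError("image pool smaller than batch_size")
    rng = np.random.default_rng(cfg.seed)

    pop = _sample_batches(
        n_images, cfg.batch_size, cfg.population,
        int(rng.integers(2**31 - 1)),
    )
    trace = []
    elite_idx = None
    for _ in range(cfg.generations):
        scores = _batch_rsa_scores(pa, pb, pop)
        key = _rank_key(scores, cfg.objective)
        order = np.lexsort((_batch_hashes(pop), key))
        elite = order[: cfg.n_elite]
        elite_idx = pop[elite]
        trace.append(float(scores[elite[0]]))
        mutated = _mutate_batches(elite_idx, cfg.mutation_counts, n_images, rng)
        fresh = _sample_batches(
            n_images, cfg.batch_size, cfg.n_random,
            int(rng.integers(2**31 - 1)),
        )
        pop = np.vstack([elite_idx, mutated, fresh])
    best_ids = ids[np.sort(elite_idx[0])]
    return best_ids, trace[-1], np.asarray(trace)


def crossval_multivariate(
    sets_a: list[ResponseSet],
    sets_b: list[ResponseSet],
    cfg: BatchSearchConfig,
    null_samples: int = 0,
) -> list[dict]:
    """Leave-one-participant-out cross-validation of the batch search.

    Per fold, the search runs on the training participants' entry-wise
    averaged RSMs; the evaluation is the RSA of the held-out participant's
    two RSMs on the selected batch.  When ``null_samples`` > 0 a baseline
    batch (and its held-out RSA) is computed per fold from the training
    participants' averaged null.
    """
    n = len(sets_a)
    if n < 2 or len(sets_b) != n:
        raise ValueError("need >= 2 participants with matching area sets")
    folds = []
    for held in range(n):
        train = [i for i in range(n) if i != held]
        batch, train_score, trace = search_controlling_batches(
            [sets_a[i] for i in train], [sets_b[i] for i in train], cfg
        )
        eval_r = rsa_score(
            compute_rsm(sets_a[held], batch), compute_rsm(sets_b[held], batch)
        ).r
        fold = {
            "fold": sets_a[held].participant,
            "image_ids": batch,
            "train_score": train_score,
            "eval_score": eval_r,
            "trace": trace,
        }
        if null_samples:
            null = build_multivariate_null(
                [sets_a[i] for i in train],
                [sets_b[i] for i in train],
                cfg.batch_size,
                null_samples,
                cfg.seed,
            )
            fold["baseline_image_ids"] = null.baseline_image_ids
            fold["baseline_eval_score"] = rsa_score(
                compute_rsm(sets_a[held], null.baseline_image_ids),
                compute_rsm(sets_b[held], null.baseline_image_ids),
            ).r
        folds.append(fold)
    return folds
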