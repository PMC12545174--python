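"""End-to-end synthetic demonstration pipeline and run provenance.

:func:`run_demo` wires every stage together on the synthetic cortex:
simulate responses, build baselines, run univariate and multivariate
control with leave-one-participant-out cross-validation, apply the
two-level statistics, and embed the areas with MDS.  The report is a
plain JSON-serializable dict, byte-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .embedding import embed_univariate, proximity_opacity
from .multivariate import BatchSearchConfig, crossval_multivariate, search_controlling_batches
from .response_store import univariate_profile
from .stats import bh_adjust, bootstrap_ci, permutation_test, prevalence_pvalue
from .synthetic_cortex import SyntheticCortexConfig, simulate_hierarchy
from .univariate import (
    UniControlCondition,
    aggregate_by_pair_group,
    build_univariate_null,
    crossval_univariate,
    profile_correlation,
    select_univariate_controls,
    stepwise_distance_grouping,
)

__all__ = ["DemoConfig", "run_demo", "provenance", "to_jsonable", "dump_report"]


@dataclass
class DemoConfig:
    """Problem sizes for the demonstration run (scaled-down defaults)."""

    cortex: SyntheticCortexConfig = field(default_factory=SyntheticCortexConfig)
    n_select: int = 25
    uni_null_samples: int = 20_000
    multi_batch: BatchSearchConfig = field(
        default_factory=lambda: BatchSearchConfig(
            population=120,
            batch_size=50,
            n_elite=10,
            mutation_counts=(1, 5, 12, 25, 38),
            n_random=60,
            generations=15,
            objective="disentangle",
        )
    )
    n_perm: int = 1000
    n_boot: int = 2000
    seed: int = 0


def provenance(cfg, seed: int) -> dict:
    """Machine-readable provenance block: config hash, seed, version."""
    blob = json.dumps(to_jsonable(cfg), sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "rnc_version": __version__,
    }


def to_jsonable(obj):
    """Recursively convert dataclasses/numpy objects to JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def dump_report(report: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(to_jsonable(report), f, sort_keys=True, indent=1)


def _condition_stat(data, _rng=None):
    control, baseline = data
    return float(np.mean(control) - np.mean(baseline))


def _shuffle_conditions(data, rng):
    control, baseline = data
    pooled = np.concatenate([control, baseline])
    perm = rng.permutation(pooled)
    return perm[: len(control)], perm[len(control) :]


def run_demo(cfg: DemoConfig) -> dict:
    """Run the full synthetic pipeline; returns the JSON-ready report."""
    stage = "simulate"
    try:
        sets, truth = simulate_hierarchy(cfg.cortex)
        participants = sorted({p for p, _ in sets})
        areas = [a.name for a in cfg.cortex.areas]
        profiles = {
            (p, a): univariate_profile(sets[(p, a)]) for p in participants for a in areas
        }

        # ---- stepwise-distance analyses on the pooled (all-participant) average
        stage = "univariate_pairs"
        avg_profiles = {}
        for a in areas:
            vals = np.mean([profiles[(p, a)].values for p in participants], axis=0)
            avg_profiles[a] = dataclasses.replace(
                profiles[(participants[0], a)], participant="average", values=vals
            )
        nulls = {
            a: build_univariate_null(
                avg_profiles[a], cfg.n_select, cfg.uni_null_samples, cfg.seed
            )
            for a in areas
        }
        pair_corr, pair_dev = {}, {}
        condition = UniControlCondition("drive_A_suppress_B")
        for i, a in enumerate(areas):
            for b in areas[i + 1 :]:
                pair_corr[(a, b)] = profile_correlation(
                    avg_profiles[a], avg_profiles[b]
                )
                sol = select_univariate_controls(
                    avg_profiles[a],
                    avg_profiles[b],
                    nulls[a].baseline_score,
                    nulls[b].baseline_score,
                    condition,
                    cfg.n_select,
                )
                sa = avg_profiles[a].as_series().loc[sol.image_ids].mean()
                sb = avg_profiles[b].as_series().loc[sol.image_ids].mean()
                pair_dev[(a, b)] = float(
                    (abs(sa - nulls[a].baseline_score) + abs(sb - nulls[b].baseline_score))
                    / 2
                )
        grouping = stepwise_distance_grouping(areas)
        dist_corr = aggregate_by_pair_group(pair_corr, grouping)
        dist_dev = aggregate_by_pair_group(pair_dev, grouping)

        # ---- cross-validated univariate control on the most distant pair
        stage = "univariate_cv"
        a0, a1 = areas[0], areas[-1]
        folds = crossval_univariate(
            [profiles[(p, a0)] for p in participants],
            [profiles[(p, a1)] for p in participants],
            condition,
            n_select=cfg.n_select,
            batch_size=cfg.n_select,
            n_null_samples=cfg.uni_null_samples,
            seed=cfg.seed,
        )

        # ---- two-level statistics on the cross-validated effect
        stage = "stats"
        p_values, effects = [], []
        for held, sol in enumerate(folds):
            prof = profiles[(participants[held], a0)].as_series()
            control = prof.loc[sol.image_ids].to_numpy()
            baseline = prof.loc[sol.eval["baseline_image_ids_A"]].to_numpy()
            res = permutation_test(
                (control, baseline),
                _condition_stat,
                _shuffle_conditions,
                n_perm=cfg.n_perm,
                sidedness="one",
                seed=cfg.seed + held,
                scheme_name="across_image_conditions",
            )
            p_values.append(res.p)
            effects.append(res.observed)
        adjusted = bh_adjust(p_values)
        k = int((adjusted < 0.05).sum())
        prevalence = prevalence_pvalue(k, len(folds))
        ci = bootstrap_ci(effects, n_boot=cfg.n_boot, seed=cfg.seed)

        # ---- multivariate control
        stage = "multivariate"
        mv_pairs = {}
        for i, a in enumerate(areas):
            for b in areas[i + 1 :]:
                _, score, trace = search_controlling_batches(
                    [sets[(p, a)] for p in participants],
                    [sets[(p, b)] for p in participants],
                    cfg.multi_batch,
                )
                mv_pairs[(a, b)] = float(score)
        dist_rsa = aggregate_by_pair_group(mv_pairs, grouping)
        mv_folds = crossval_multivariate(
            [sets[(p, a0)] for p in participants],
            [sets[(p, a1)] for p in participants],
            cfg.multi_batch,
        )

        # ---- embeddings
        stage = "embedding"
        emb = embed_univariate(
            {a: avg_profiles[a].values for a in areas}, seed=cfg.seed
        )
        opacity = proximity_opacity(emb.embedded_distances())
    except Exception as err:
        return {
            "status": "aborted",
            "stage": stage,
            "cause": f"{type(err).__name__}: {err}",
            "provenance": provenance(cfg, cfg.seed),
        }

    return {
        "status": "ok",
        "provenance": provenance(cfg, cfg.seed),
        "areas": areas,
        "baselines": {a: nulls[a].baseline_score for a in areas},
        "stepwise_distance": {
            "profile_correlation": {int(k): float(v) for k, v in dist_corr.items()},
            "disentangle_abs_deviation": {int(k): float(v) for k, v in dist_dev.items()},
            "disentangle_rsa": {int(k): float(v) for k, v in dist_rsa.items()},
        },
        "univariate_cv": {
            "condition": condition.label,
            "pair": [a0, a1],
            "folds": [
                {
                    "fold": sol.fold,
                    "n_selected": sol.n_selected,
                    "eval": {
                        k: v
                        for k, v in sol.eval.items()
                        if not k.startswith("baseline_image_ids")
                    },
                }
                for sol in folds
            ],
        },
        "statistics": {
            "per_participant_p": [float(p) for p in p_values],
            "bh_adjusted_p": [float(p) for p in adjusted],
            "k_significant": k,
            "prevalence_P": prevalence.P,
            "effect_ci": [ci.lower, ci.upper],
        },
        "multivariate_cv": {
            "pair": [a0, a1],
            "objective": cfg.multi_batch.objective,
            "folds": [
                {
                    "fold": f["fold"],
                    "train_score": float(f["train_score"]),
                    "eval_score": float(f["eval_score"]),
                }
                for f in mv_folds
            ],
        },
        "embedding": {
            "areas": emb.areas,
            "coords": emb.coords,
            "stress": emb.stress,
            "opacity": opacity,
        },
    }
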