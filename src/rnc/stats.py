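"""Two-level statistical inference for small intensely-sampled cohorts.

First level: within-participant non-parametric permutation tests (the p
value is the plain proportion of randomized statistics at least as
extreme as the observed one), corrected across tests with
Benjamini-Hochberg.  Second level: population prevalence — the count k of
within-participant-significant participants out of n is referred to the
binomial tail P = 1 - CDF(k; n, alpha), the chance of that many
significant participants if no member of the population had the effect.
Bootstrap confidence intervals resample participants with replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "PrevalenceResult",
    "BootstrapCI",
    "permutation_test",
    "bh_adjust",
    "prevalence_pvalue",
    "bootstrap_ci",
]

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed: float
    n_perm: int
    p: float
    sidedness: str
    scheme: str


@dataclass
class PrevalenceResult:
    k: int
    n: int
    a: float
    P: float


@dataclass
class BootstrapCI:
    n_boot: int
    level: float
    lower: float
    upper: float


def permutation_test(
    data,
    statistic,
    scheme,
    n_perm: int = 100_000,
    sidedness: str = "two",
    seed: int = 0,
    add_one: bool = False,
    scheme_name: str | None = None,
) -> PermutationResult:
    """Generic within-participant permutation test.

    Parameters
    ----------
    data
        Any object the two callables understand.
    statistic
        ``statistic(data) -> float``, the quantity of interest.
    scheme
        ``scheme(data, rng) -> data`` returning one exchanged copy; this
        encodes the exchangeability assumption of the analysis (e.g.
        permuting responses across image conditions, across areas, or
        across voxels and predictors).
    sidedness
        "two": extremeness is |stat - H0 centre| with the null centre
        taken as the permutation mean; "one": larger is more extreme.
    add_one
        When True, apply (b+1)/(m+1) smoothing instead of the plain
        proportion.

    A permutation on which the statistic is undefined (NaN) is rejected
    and resampled (logged), up to a 10x resampling budget.
    """
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    rng = np.random.default_rng(seed)
    observed = float(statistic(data))
    null = np.empty(n_perm)
    got, attempts = 0, 0
    while got < n_perm:
        if attempts > 10 * n_perm:
            raise RuntimeError("too many undefined permutation statistics")
        value = float(statistic(scheme(data, rng)))
        attempts += 1
        if np.isnan(value):
            logger.info("statistic undefined on a permutation; resampled")
            continue
        null[got] = value
        got += 1
    if sidedness == "one":
        extreme = null >= observed
    else:
        centre = null.mean()
        extreme = np.abs(null - centre) >= np.abs(observed - centre)
    if add_one:
        p = (extreme.sum() + 1) / (n_perm + 1)
    else:
        p = extreme.mean()
    return PermutationResult(
        observed=observed,
        n_perm=n_perm,
        p=float(p),
        sidedness=sidedness,
        scheme=scheme_name or getattr(scheme, "__name__", "custom"),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def prevalence_pvalue(k: int, n: int, a: float = 0.05) -> PrevalenceResult:
    """Population prevalence p value: P = 1 - BinomCDF(k; n, a).

    This is the probability of observing *more than* k significant
    participants out of n when each is significant with probability a
    under the global null.
    """
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    P = float(1.0 - sps.binom.cdf(k, n, a))
    return PrevalenceResult(k=k, n=n, a=a, P=P)


def bootstrap_ci(
    per_participant_values,
    n_boot: int = 100_000,
    level: float = 95.0,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI for the participant mean."""
    values = np.asarray(per_participant_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(100 - level) / 2, 100 - (100 - level) / 2])
    return BootstrapCI(n_boot=n_boot, level=level, lower=float(lo), upper=float(hi))
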