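"""Inferential statistics for tuning-behavior comparisons.

Three tools tie neural tuning to behavior:

* a Pearson correlation between normalized tuning-curve means, with a
  permutation null built by shuffling the condition (IPI) labels of one
  curve — exhaustive enumeration for small n, seeded Monte Carlo with the
  add-one correction otherwise;
* Meng, Rosenthal & Rubin's z-test for comparing two dependent correlations
  that share one variable (here: two neuron classes against the same
  behavioral curve);
* Wilcoxon rank-sum and signed-rank tests (exact enumeration for small,
  tie-free samples; normal approximation with tie correction otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "MengResult",
    "pearson_r",
    "permutation_corr_test",
    "meng_z",
    "wilcoxon",
    "holm",
]

#: Exhaustive enumeration is used when n! is at most this.
EXHAUSTIVE_LIMIT = 500_000

#: Numerical tolerance when counting null correlations >= the observed one.
_TIE_EPS = 1e-12


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


@dataclass
class PermutationResult:
    """Observed correlation and its permutation null."""

    r_observed: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    sided: str
    seed: int | None = None
    null_mean: float = 0.0
    null_sd: float = 0.0

    def to_dict(self) -> dict:
        return {"test": "permutation_corr", "r": self.r_observed,
                "p": self.p_value, "n_perm": self.n_permutations,
                "exhaustive": self.exhaustive, "sided": self.sided,
                "seed": self.seed}


def _null_correlations_exhaustive(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    perms = np.array(list(permutations(range(len(y)))))
    return _corr_many(x, y[perms])


def _corr_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of x against every row of Y, vectorized."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = Yc @ xc
    den = np.sqrt((xc @ xc) * (Yc * Yc).sum(axis=1))
    return num / den


def permutation_corr_test(x, y, n_perm: int = 10_000, seed: int | None = None,
                          sided: str = "greater",
                          method: str = "auto") -> PermutationResult:
    """Significance of corr(x, y) under random permutation of y's labels.

    ``method`` is 'auto' (exhaustive when n! <= 500,000, else Monte Carlo),
    'exact', or 'mc'.  The exhaustive p is the fraction of all n! label
    orders whose correlation meets the observed one (the identity order
    counts itself, so p >= 1/n!) and is seed-independent.  Monte Carlo uses
    the add-one correction p = (1 + hits) / (1 + n_perm) and requires a
    seed.  ``sided``: 'greater' (positive correlation), 'less', or
    'two-sided' (on |r|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = pearson_r(x, y)
    n = len(x)
    if sided not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown sidedness {sided!r}")

    exhaustive = method == "exact" or (
        method == "auto" and math.factorial(n) <= EXHAUSTIVE_LIMIT)
    if exhaustive:
        null = _null_correlations_exhaustive(x, y)
        n_used = len(null)
        p = _tail_fraction(null, r_obs, sided)
        used_seed = None
    else:
        if seed is None:
            raise ValueError("Monte Carlo permutation test requires a seed")
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        null = _corr_many(x, y[idx])
        n_used = n_perm
        hits = _tail_count(null, r_obs, sided)
        p = (1 + hits) / (1 + n_perm)
        used_seed = seed
    return PermutationResult(r_obs, float(p), n_used, exhaustive, sided,
                             used_seed, float(null.mean()), float(null.std()))


def _tail_count(null: np.ndarray, r_obs: float, sided: str) -> int:
    if sided == "greater":
        return int(np.sum(null >= r_obs - _TIE_EPS))
    if sided == "less":
        return int(np.sum(null <= r_obs + _TIE_EPS))
    return int(np.sum(np.abs(null) >= abs(r_obs) - _TIE_EPS))


def _tail_fraction(null: np.ndarray, r_obs: float, sided: str) -> float:
    return _tail_count(null, r_obs, sided) / len(null)


# ---------------------------------------------------------------------------
# Meng's z-test for dependent correlations
# ---------------------------------------------------------------------------

@dataclass
class MengResult:
    """z statistic and p-value comparing two dependent correlations."""

    z: float
    p_value: float
    r1: float
    r2: float
    r_x: float
    n: int
    sided: str

    def to_dict(self) -> dict:
        return {"test": "meng_z", "z": self.z, "p": self.p_value,
                "r1": self.r1, "r2": self.r2, "r_x": self.r_x,
                "n": self.n, "sided": self.sided}


def meng_z(r1: float, r2: float, r_x: float, n: int,
           sided: str = "two-sided") -> MengResult:
    """Meng-Rosenthal-Rubin test of H0: rho1 = rho2 for correlations of two
    predictors with a common criterion.

    ``r1`` and ``r2`` are the two criterion correlations, ``r_x`` the
    correlation between the two predictors, ``n`` the number of paired
    observations.  With Fisher transforms z1, z2 and rbar2 = (r1^2+r2^2)/2:

        f = min(1, (1 - r_x) / (2 (1 - rbar2)))
        h = (1 - f rbar2) / (1 - rbar2)
        z = (z1 - z2) sqrt((n - 3) / (2 (1 - r_x) h))
    """
    for name, r in (("r1", r1), ("r2", r2)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly within (-1, 1)")
    if not -1.0 <= r_x < 1.0:
        raise ValueError("r_x must lie in [-1, 1); r_x = 1 makes the "
                         "comparison undefined")
    if n < 4:
        raise ValueError("need n >= 4 paired observations")

    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar2 = (r1 ** 2 + r2 ** 2) / 2.0
    f = min(1.0, (1.0 - r_x) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r_x) * h))

    if sided == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif sided == "greater":     # H1: rho1 > rho2
        p = sps.norm.sf(z)
    elif sided == "less":
        p = sps.norm.cdf(z)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return MengResult(float(z), float(p), r1, r2, r_x, n, sided)


# ---------------------------------------------------------------------------
# Wilcoxon tests
# ---------------------------------------------------------------------------

_ALT = {"two-sided": "two-sided", "greater": "greater", "less": "less"}


def wilcoxon(a, b, mode: str = "rank_sum", sided: str = "two-sided") -> float:
    """Wilcoxon rank-sum (independent) or signed-rank (paired) p-value.

    Rank-sum uses exact enumeration for tie-free samples with combined
    n <= 20, otherwise the tie-corrected normal approximation.  Signed-rank
    drops zero differences; if every difference is zero the test carries no
    information and p = 1 by convention.  ``sided`` refers to a vs b
    ('greater': a tends larger).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if sided not in _ALT:
        raise ValueError(f"unknown sidedness {sided!r}")

    if mode == "rank_sum":
        combined = np.concatenate([a, b])
        ties = len(np.unique(combined)) < len(combined)
        exact = (len(combined) <= 20) and not ties
        res = sps.mannwhitneyu(a, b, alternative=_ALT[sided],
                               method="exact" if exact else "asymptotic")
        return float(res.pvalue)
    if mode == "signed_rank":
        if len(a) != len(b):
            raise ValueError("signed-rank test needs paired samples")
        d = a - b
        if np.all(d == 0):
            return 1.0
        nz = int(np.sum(d != 0))
        method = "exact" if nz <= 20 and len(np.unique(np.abs(d[d != 0]))) == nz \
            else "approx"
        res = sps.wilcoxon(a, b, alternative=_ALT[sided],
                           zero_method="wilcox", method=method)
        return float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def holm(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
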