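"""Statistical kernels shared by the null models and network modules.

Thin, explicitly-contracted wrappers: Spearman and Wilcoxon delegate to
scipy, the Mantel permutation test and Bray-Curtis are implemented here
(seeded, with the exact p-value convention the null models rely on), and
alpha diversity combines richness, Chao1 and ACE.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from skbio.diversity.alpha import ace as _skbio_ace

from .core import DistanceMatrix, ValidationError

__all__ = [
    "TestResult",
    "AlphaDiversity",
    "spearman_rho_p",
    "spearman_exact_p",
    "wilcoxon_rank_sum",
    "mantel_test",
    "bray_curtis",
    "bray_curtis_condensed",
    "alpha_diversity",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValidationError(f"p-value out of [0,1]: {self.p_value}")


@dataclass
class AlphaDiversity:
    richness: int
    chao1: float
    ace: float


# ---------------------------------------------------------------------------
# correlation / rank tests
# ---------------------------------------------------------------------------


def spearman_rho_p(x, y) -> TestResult:
    """Spearman rank correlation with a two-sided t-approximation p.

    Mid-ranks for ties; a constant vector makes rho undefined (NaN result
    flagged in the method note).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValidationError("need n >= 4 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(np.nan, np.nan, "spearman (undefined: constant input)", n)
    rho, p = sps.spearmanr(x, y)
    if abs(rho) >= 1.0 - 1e-12:
        p = 0.0
    return TestResult(float(rho), float(p), "spearman, t approximation", n)


def spearman_exact_p(x, y) -> TestResult:
    """Exact two-sided permutation p for Spearman rho (small n, test oracle).

    Enumerates all n! orderings of y; feasible for n <= ~8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 8:
        raise ValidationError("exact enumeration limited to n <= 8")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return TestResult(float(obs), count / total, "spearman, exact permutation", n)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when n_x + n_y <= 12 with no ties, otherwise the
    normal approximation with tie and continuity corrections.  The
    statistic reported is the rank sum of ``x``.  Two-sided p is
    2 x min(one-sided), capped at 1; fully tied data give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence either way
        rank_sum = nx * (nx + ny + 1) / 2
        return TestResult(rank_sum, 1.0, "wilcoxon rank-sum (degenerate ties)", nx + ny)
    if nx + ny <= 12 and not has_ties:
        res = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        method = "wilcoxon rank-sum, exact"
    else:
        res = sps.mannwhitneyu(
            x, y, method="asymptotic", use_continuity=True, alternative="two-sided"
        )
        method = "wilcoxon rank-sum, normal approximation"
    rank_sum = float(res.statistic) + nx * (nx + 1) / 2.0
    p = float(min(res.pvalue, 1.0))
    if np.isnan(p):
        p = 1.0
    return TestResult(rank_sum, p, method, nx + ny)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def mantel_test(
    Da: DistanceMatrix,
    Db: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
    method: str = "pearson",
) -> TestResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson (or Spearman) correlation of the upper triangles;
    the one-sided p is ``(1 + #{permuted r >= observed r}) / (permutations
    + 1)``, permuting rows and columns of ``Db`` jointly, so p can never
    drop below 1/(permutations+1).
    """
    if Da.labels != Db.labels:
        raise ValidationError("matrices must share labels in the same order")
    n = len(Da.labels)
    iu, ju = np.triu_indices(n, k=1)
    a = Da.values[iu, ju]
    B = Db.values

    if method == "spearman":
        a = sps.rankdata(a)

        def flat(M):
            return sps.rankdata(M[iu, ju])
    elif method == "pearson":
        def flat(M):
            return M[iu, ju]
    else:
        raise ValidationError(f"unknown method {method!r}")

    def corr(u, v):
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            return np.nan
        return np.corrcoef(u, v)[0, 1]

    obs = corr(a, flat(B))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        r = corr(a, flat(B[np.ix_(p, p)]))
        if not np.isnan(r) and r >= obs - 1e-12:
            exceed += 1
    p_value = (1 + exceed) / (permutations + 1)
    return TestResult(float(obs), p_value, f"mantel ({method}), {permutations} perms", n)


# ---------------------------------------------------------------------------
# dissimilarity and alpha diversity
# ---------------------------------------------------------------------------


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1].

    Two all-zero vectors have no defined dissimilarity -> NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("vectors must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        return np.nan
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_condensed(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis between columns, as a square matrix."""
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(np.asarray(matrix, dtype=float).T, metric="braycurtis"))


def _chao1(counts: np.ndarray) -> float:
    s = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s + f1 * f1 / (2.0 * f2)
    # bias-corrected form when no doubletons
    return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(counts) -> AlphaDiversity:
    """Richness, Chao1 and ACE for one sample's integer count vector.

    Chao1 uses the classic S + F1^2/(2 F2) estimator, switching to the
    bias-corrected form when there are no doubletons.  ACE uses the
    abundance-based coverage estimator with the conventional rare-species
    cutoff of 10.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValidationError("all-zero sample has no diversity")
    richness = int((counts > 0).sum())
    chao1 = _chao1(counts)
    try:
        ace = float(_skbio_ace(counts[counts > 0].astype(int), rare_threshold=10))
    except (ZeroDivisionError, ValueError):
        # no rare class or coverage zero: estimator undefined, fall back
        ace = float(richness)
    if np.isnan(ace):
        ace = float(richness)
    return AlphaDiversity(richness=richness, chao1=float(chao1), ace=ace)
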