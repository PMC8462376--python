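"""Statistical kernel: dissimilarities, permutation tests, rank tests.

Everything here is implemented directly rather than delegated, because
the permutation conventions (add-one p-values, exhaustive enumeration at
small n, seeded reproducibility) are contractual for the pipeline.
Established libraries are used as independent cross-checks in the test
suite only.

Conventions
-----------
* Permutation p-values follow the add-one ("include the observed")
  convention: p = (1 + #{stat_perm >= stat_obs}) / (n_permutations + 1).
* When the number of distinct label orderings n! does not exceed
  n_permutations + 1, tests enumerate all n! orderings exhaustively and
  report p = #{stat_perm >= stat_obs} / n!  (the identity ordering plays
  the role of the observed draw, so the convention is consistent).
* All stochastic operations take an explicit integer seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

__all__ = [
    "DistanceMatrix",
    "PermutationTestResult",
    "TestResult",
    "bray_curtis",
    "geographic_distance",
    "permanova",
    "mantel",
    "wilcoxon_rank_sum",
    "t_test_two_sample",
    "benjamini_hochberg",
]

_STAT_TOL = 1e-12  # tie tolerance when comparing permuted statistics


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric distance matrix with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        return squareform(self.values, checks=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    exhaustive: bool = False
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.degenerate and not self.exhaustive:
            if self.p_value < 1.0 / (self.n_permutations + 1) - 1e-15:
                raise ValueError("p-value below add-one floor")


@dataclass(frozen=True)
class TestResult:
    """Result of a classical two-sample test."""

    statistic: float
    p_value: float
    df: float | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# distances


def bray_curtis(abundance, labels=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x-y| / sum(x+y).

    Singleton OTUs are retained: community-dissimilarity analyses use the
    unfiltered table.  A pair of samples that are both entirely zero has
    undefined dissimilarity and raises a ValueError naming the samples.
    """
    X = _as_matrix(abundance)
    if labels is None:
        labels = _labels_of(abundance, X.shape[0])
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero) >= 2:
        bad = [labels[i] for i in zero]
        raise ValueError(f"Bray-Curtis undefined for all-zero sample pairs: {bad}")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        num = np.abs(X[i] - X[i + 1 :]).sum(axis=1)
        den = (X[i] + X[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return DistanceMatrix(tuple(labels), D)


def bray_curtis_pairs(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise BC between matched rows of two equally shaped matrices."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    num = np.abs(A - B).sum(axis=1)
    den = (A + B).sum(axis=1)
    if (den == 0).any():
        raise ValueError("Bray-Curtis undefined: a pair of all-zero samples")
    return num / den


def geographic_distance(coords, labels=None) -> DistanceMatrix:
    """Pairwise Euclidean distances in meters between (x, y) points."""
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array of (x, y) meters")
    if not np.isfinite(pts).all():
        raise ValueError("coordinates must be finite")
    if labels is None:
        labels = [str(i) for i in range(len(pts))]
    D = squareform(pdist(pts)) if len(pts) > 1 else np.zeros((1, 1))
    return DistanceMatrix(tuple(labels), D)


# ---------------------------------------------------------------------------
# permanova


def _permanova_F(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float, bool]:
    """Pseudo-F and R^2 from the Gower-centered squared-distance identity.

    SS_total = (1/n) sum_{i<j} d_ij^2 ;
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2 ;
    F = (SS_between / (g-1)) / (SS_within / (n-g)).
    """
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_total <= _STAT_TOL:
        return math.nan, math.nan, True
    r2 = ss_between / ss_total
    if ss_within <= _STAT_TOL:
        return math.inf, r2, False
    F = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return F, r2, False


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """One-way permutational multivariate ANOVA on a distance matrix.

    ``groups`` maps sample label to group label (mapping or sequence
    aligned with ``dist.labels``).  The p-value comes from random
    relabelings, or from exhaustive enumeration of all n! orderings when
    n! <= n_permutations + 1.  R^2 = SS_between / SS_total is attached in
    ``extras``.
    """
    labels = list(dist.labels)
    if callable(getattr(groups, "get", None)):
        glabels = [groups[s] for s in labels]
    else:
        glabels = list(groups)
        if len(glabels) != len(labels):
            raise ValueError("groups length does not match distance matrix")
    uniq = list(dict.fromkeys(glabels))
    g = len(uniq)
    if g < 2:
        raise ValueError("permanova requires at least 2 groups")
    codes = np.array([uniq.index(x) for x in glabels])
    n = len(codes)
    if n - g <= 0:
        raise ValueError(f"residual degrees of freedom n-g = {n - g} <= 0")
    d2 = dist.values**2
    F_obs, r2, degenerate = _permanova_F(d2, codes, g)
    if degenerate:
        return PermutationTestResult(
            math.nan, math.nan, n_permutations, seed, degenerate=True, extras={"R2": math.nan}
        )

    if math.factorial(n) <= n_permutations + 1:
        count, total = 0, 0
        for perm in itertools.permutations(range(n)):
            Fp, _, _ = _permanova_F(d2, codes[list(perm)], g)
            total += 1
            if Fp >= F_obs - _STAT_TOL:
                count += 1
        return PermutationTestResult(
            F_obs, count / total, total, seed, exhaustive=True, extras={"R2": r2}
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        Fp, _, _ = _permanova_F(d2, codes[rng.permutation(n)], g)
        if Fp >= F_obs - _STAT_TOL:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return PermutationTestResult(F_obs, p, n_permutations, seed, extras={"R2": r2})


# ---------------------------------------------------------------------------
# Mantel


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> PermutationTestResult:
    """Mantel test: Pearson correlation of two distance matrices.

    The statistic is the correlation of the condensed upper triangles;
    the null distribution permutes rows/columns of ``d2`` jointly.
    One-sided "greater" by default (does similarity decay with
    distance?); "two-sided" supported.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels in the same order")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    n = d1.n
    x = d1.condensed()
    V2 = d2.values
    y = squareform(V2, checks=False)
    if x.std() == 0 or y.std() == 0:
        return PermutationTestResult(math.nan, math.nan, n_permutations, seed, degenerate=True)

    xc = (x - x.mean()) / x.std()

    def corr_with(perm: np.ndarray) -> float:
        yp = squareform(V2[np.ix_(perm, perm)], checks=False)
        return float(np.dot(xc, (yp - yp.mean()) / yp.std()) / len(x))

    r_obs = float(np.corrcoef(x, y)[0, 1])
    key = abs if alternative == "two-sided" else (lambda v: v)
    obs = key(r_obs)

    if math.factorial(n) <= n_permutations + 1:
        count, total = 0, 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if key(corr_with(np.array(perm))) >= obs - _STAT_TOL:
                count += 1
        return PermutationTestResult(r_obs, count / total, total, seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if key(corr_with(rng.permutation(n))) >= obs - _STAT_TOL:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return PermutationTestResult(r_obs, p, n_permutations, seed)


# ---------------------------------------------------------------------------
# rank and t tests


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration of rank assignments when n_a + n_b <= 12 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    na, nb = len(a), len(b)
    n = na + nb
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    # midranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    W = float(ranks[:na].sum())
    has_ties = len(np.unique(pooled)) < n

    if n <= 12 and not has_ties:
        # exact: rank sum of a under random assignment of ranks 1..n
        all_ranks = np.arange(1, n + 1)
        sums = np.array([sum(c) for c in itertools.combinations(all_ranks, na)], dtype=float)
        total = len(sums)
        p_le = np.count_nonzero(sums <= W + 1e-9) / total
        p_ge = np.count_nonzero(sums >= W - 1e-9) / total
        p = min(1.0, 2 * min(p_le, p_ge))
        return TestResult(W, p)

    mean = na * (n + 1) / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if has_ties else 0.0
    var = na * nb / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(W, 1.0, degenerate=True)
    z = (W - mean - 0.5 * np.sign(W - mean)) / math.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return TestResult(W, min(1.0, p))


def t_test_two_sample(a, b, variant: str = "welch") -> TestResult:
    """Two-sided two-sample t-test (Welch by default, pooled optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs length >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, degenerate=True)
        return TestResult(math.inf, 0.0, degenerate=True)
    if variant == "welch":
        se2 = va / na + vb / nb
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    elif variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        raise ValueError("variant must be 'welch' or 'pooled'")
    from scipy.stats import t as t_dist

    p = float(2 * t_dist.sf(abs(t), df))
    return TestResult(float(t), p, df=float(df))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------


def _as_matrix(abundance) -> np.ndarray:
    X = np.asarray(getattr(abundance, "values", abundance), dtype=float)
    if X.ndim != 2:
        raise ValueError("abundance must be a 2-D samples x OTUs matrix")
    return X


def _labels_of(abundance, n: int) -> list[str]:
    import pandas as pd

    if isinstance(abundance, (pd.DataFrame, pd.Series)):
        return [str(s) for s in abundance.index]
    return [str(i) for i in range(n)]
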