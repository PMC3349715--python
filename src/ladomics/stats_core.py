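"""Statistical primitives shared by every association stage.

Conventions
-----------
* ``fisher_exact`` — exact conditional test given margins. 2x2 tables go
  through the classical hypergeometric test (two-sided p = sum of table
  probabilities <= observed); 2x3 tables are enumerated exactly over the
  margin-fixed fiber with the same sum-of-probabilities definition.
* ``kruskal_wallis`` — H with midrank tie correction; chi-square p on k-1
  degrees of freedom. When every value is identical the statistic is 0 and
  p = 1 by convention.
* ``wilcoxon_rank_sum`` — exact enumeration when the pooled size is <= 12
  and there are no ties, otherwise the normal approximation with tie and
  continuity correction. The switchover is fixed for reproducibility.
* ``bh_adjust`` — Benjamini-Hochberg step-up q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

TWO_SIDED = "two_sided"
ONE_SIDED_GREATER = "one_sided_greater"

#: pooled-size bound below which rank-sum p-values are computed exactly
EXACT_RANKSUM_MAX_N = 12

#: relative tolerance when summing "as or more extreme" table probabilities
_FISHER_RTOL = 1e-7


@dataclass
class TestResult:
    statistic: float
    p_value: float
    sidedness: str = TWO_SIDED
    n_per_group: tuple[int, ...] = ()
    flag: str = ""

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = float(min(self.p_value, 1.0))


def _validate_table(table: np.ndarray) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(arr < 0):
        raise ValueError("contingency table has negative cells")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError("contingency table has non-integer cells")
    return arr.astype(np.int64)


def _fisher_2x3_two_sided(table: np.ndarray) -> float:
    """Exact two-sided p for a 2x3 table by fiber enumeration.

    p = sum of probabilities of all margin-compatible tables whose
    conditional probability is <= that of the observed table.
    """
    r1 = int(table[0].sum())
    cols = table.sum(axis=0).astype(int)
    n = int(table.sum())
    if n == 0:
        return 1.0
    logfact = gammaln(np.arange(n + 1) + 1.0)

    def log_binom(m: np.ndarray | int, k: np.ndarray) -> np.ndarray:
        return logfact[m] - logfact[k] - logfact[np.asarray(m) - k]

    a = np.arange(0, min(r1, cols[0]) + 1)
    b = np.arange(0, min(r1, cols[1]) + 1)
    A, B = np.meshgrid(a, b, indexing="ij")
    C = r1 - A - B
    valid = (C >= 0) & (C <= cols[2])
    Cc = np.clip(C, 0, cols[2])
    logp = (
        log_binom(cols[0], A)
        + log_binom(cols[1], B)
        + log_binom(cols[2], Cc)
        - (logfact[n] - logfact[r1] - logfact[n - r1])
    )
    logp = np.where(valid, logp, -np.inf)
    obs = logp[int(table[0, 0]), int(table[0, 1])]
    mask = logp <= obs + np.log1p(_FISHER_RTOL)
    return float(min(np.exp(logp[valid & mask]).sum(), 1.0))


def fisher_exact(table, sidedness: str = TWO_SIDED) -> TestResult:
    """Fisher's exact test on a 2x2 or 2x3 (or 3x2) contingency table.

    For ``one_sided_greater`` the table must be 2x2 and the declared
    direction is "cell (0, 0) larger than expected under independence".
    """
    arr = _validate_table(table)
    if arr.shape in ((3, 2),):
        arr = arr.T
    if sidedness == ONE_SIDED_GREATER:
        if arr.shape != (2, 2):
            raise ValueError("one-sided Fisher test requires a 2x2 table")
        stat, p = stats.fisher_exact(arr, alternative="greater")
    elif arr.shape == (2, 2):
        stat, p = stats.fisher_exact(arr, alternative="two-sided")
    elif arr.shape == (2, 3):
        p = _fisher_2x3_two_sided(arr)
        stat = float("nan")
    else:
        raise ValueError(f"unsupported table shape {arr.shape}; need 2x2 or 2x3")
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        sidedness=sidedness,
        n_per_group=tuple(int(c) for c in arr.sum(axis=0)),
    )


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups of reals."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    sizes = tuple(int(a.size) for a in arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # all values identical: no evidence against the null, by convention
        return TestResult(0.0, 1.0, TWO_SIDED, sizes)
    h, p = stats.kruskal(*arrays)
    return TestResult(float(h), float(p), TWO_SIDED, sizes)


def wilcoxon_rank_sum(x, y, sidedness: str = TWO_SIDED) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of x versus y.

    ``one_sided_greater`` tests the alternative that x is stochastically
    greater than y. Returns the Mann-Whitney U statistic for x.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    alternative = "greater" if sidedness == ONE_SIDED_GREATER else "two-sided"
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (xa.size + ya.size <= EXACT_RANKSUM_MAX_N) and not has_ties
    method = "exact" if exact else "asymptotic"
    if np.all(pooled == pooled[0]):
        return TestResult(
            float(xa.size * ya.size / 2.0), 1.0, sidedness,
            (int(xa.size), int(ya.size)), flag="constant input",
        )
    res = stats.mannwhitneyu(xa, ya, alternative=alternative, method=method)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return TestResult(
        float(res.statistic), p, sidedness, (int(xa.size), int(ya.size))
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation with midrank ties; t-approximation p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return TestResult(
            float("nan"), float("nan"), TWO_SIDED, (int(xa.size),),
            flag="zero rank variance: correlation undefined",
        )
    rho, p = stats.spearmanr(xa, ya)
    return TestResult(float(rho), float(p), TWO_SIDED, (int(xa.size),))


def bootstrap_ci(
    values,
    statistic: str = "median",
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap confidence interval for a mean or median."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if statistic not in ("median", "mean"):
        raise ValueError(f"unsupported statistic {statistic!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, v.size, size=(int(n_reps), v.size))
    reps = v[idx]
    stat = np.median(reps, axis=1) if statistic == "median" else reps.mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stat, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
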