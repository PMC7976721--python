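"""Cross-species statistics on B-chromosome gene content.

The chance that two B chromosomes share k of n genes if genes land on the
extra chromosome independently is modelled as a binomial with per-gene
coincidence probability p = 1/haploid chromosome number (1/25 here, the
haploid number of the study genus).  The point probability is evaluated in
log space via log-gamma, so large n (hundreds of genes) needs no factorial
arithmetic; the percent-scaled variant (k and n rescaled to percentages of
100) is also reported.  Gene-content similarity between species is the
Euclidean distance between binary B-linkage columns, compared against
mitochondrial sequence p-distances with a one-tailed Mantel permutation
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from skbio import DistanceMatrix


@dataclass(frozen=True)
class CoincidenceTest:
    n: int
    k: int
    p: float
    pmf: float
    pmf_percent_scale: float  # pmf recomputed on (100, round(100 k/n))


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int


def binom_pmf(n: int, k: int, p: float) -> float:
    """Binomial point probability C(n,k) p^k (1-p)^(n-k) via log-gamma."""
    log_pmf = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * math.log(p) + (n - k) * math.log1p(-p)
    )
    return float(math.exp(log_pmf))


def binom_coincidence(n: int, k: int, p: float) -> CoincidenceTest:
    """Likelihood of k chance gene-content coincidences out of n."""
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0 < p < 1):
        raise ValueError(f"require 0 < p < 1, got p={p}")
    k100 = round(100 * k / n)
    return CoincidenceTest(
        n=n, k=k, p=p,
        pmf=binom_pmf(n, k, p),
        pmf_percent_scale=binom_pmf(100, k100, p),
    )


GAP_OR_AMBIGUOUS = set("-.NnRYSWKMBDHVryswkmbdhv?")


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites, pairwise-deleting gaps/ambiguities."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    compared = 0
    diffs = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in GAP_OR_AMBIGUOUS or b in GAP_OR_AMBIGUOUS:
            continue
        compared += 1
        if a != b:
            diffs += 1
    if compared == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return diffs / compared


def p_distance_matrix(seqs: dict[str, str]) -> DistanceMatrix:
    labels = list(seqs)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = p_distance(seqs[labels[i]], seqs[labels[j]])
    return DistanceMatrix(m, ids=labels)


def gene_content_distances(matrix: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between species' binary gene-content columns.

    ``matrix`` is genes x species with entries in {0, 1} (1 = B-linked,
    validated).  d(s, t) = sqrt(#genes whose indicators differ).
    """
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("gene-content matrix entries must be 0 or 1")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two species columns")
    labels = [str(c) for c in matrix.columns]
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = math.sqrt(int(np.sum(vals[:, i] != vals[:, j])))
    return DistanceMatrix(m, ids=labels)


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 10000, seed: int = 0
) -> MantelResult:
    """One-tailed Mantel test for positive association of two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the null is
    generated by relabeling one matrix with random permutations and the
    one-tailed p-value is (#{r_perm >= r_obs} + 1) / (n_perm + 1).
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share labels in the same order")
    n = d1.shape[0]
    if n < 3:
        raise ValueError("need at least 3 labels")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    m1 = np.asarray(d1.data, dtype=float)
    m2 = np.asarray(d2.data, dtype=float)
    x = _upper(m1)
    r_obs = float(np.corrcoef(x, _upper(m2))[0, 1])

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    x_c = x - x.mean()
    x_den = math.sqrt(float(np.sum(x_c**2)))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y = m2[np.ix_(perm, perm)][iu]
        y_c = y - y.mean()
        den = x_den * math.sqrt(float(np.sum(y_c**2)))
        r_perm = float(np.dot(x_c, y_c) / den) if den > 0 else 0.0
        if r_perm >= r_obs - 1e-12:
            count += 1
    return MantelResult(
        r=r_obs, p_value=(count + 1) / (n_perm + 1), n_perm=n_perm, seed=seed
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with its t statistic.

    rho uses average ranks for ties; t = rho * sqrt((n-2) / (1-rho^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if abs(rho) >= 1.0:
        t = math.inf if rho > 0 else -math.inf
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return rho, t
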