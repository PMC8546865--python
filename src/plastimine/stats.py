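"""Ecological statistics used by the survey analyses.

Tie-aware Spearman rank correlation, rank-sum (Mann-Whitney) habitat scans
with an exact enumeration backend at small sizes, one-tailed Fisher
enrichment on 2x2 tables, Bray-Curtis dissimilarity and classical
principal-coordinate analysis with positive-eigenvalue variance fractions.

Two-tailed tests are the default throughout; one-tailed alternatives are
used only where a directional claim is being tested (Fisher enrichment,
directional habitat comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # n_samples x k
    variance_explained: np.ndarray  # fractions per retained axis
    eigenvalues: np.ndarray  # all eigenvalues, descending


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rho with average ranks for ties; two-sided p from the
    t approximation with n-2 degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationResult(float("nan"), float("nan"), n, degenerate=True)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), n)


def _exact_rank_sum_p(pooled_ranks: np.ndarray, n1: int, w_obs: float, alternative: str) -> float:
    """Exact permutation distribution of the group rank sum by full
    enumeration of C(n, n1) label assignments (tie-aware via shared ranks)."""
    idx = range(pooled_ranks.size)
    sums = np.fromiter(
        (pooled_ranks[list(c)].sum() for c in combinations(idx, n1)), dtype=float
    )
    eps = 1e-9
    p_ge = float(np.mean(sums >= w_obs - eps))
    p_le = float(np.mean(sums <= w_obs + eps))
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def rank_sum(
    group: Sequence[float],
    rest: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Rank-sum test of ``group`` against ``rest``.

    Returns (rank sum of the group, p). For combined n <= exact_max_n the
    p-value comes from full enumeration of the permutation distribution;
    larger samples use the tie-corrected normal approximation.
    """
    g = np.asarray(group, float)
    r = np.asarray(rest, float)
    if g.size == 0 or r.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([g, r])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: g.size].sum())
    if pooled.size <= exact_max_n:
        p = _exact_rank_sum_p(ranks, g.size, w, alternative)
    else:
        _, p = sps.mannwhitneyu(g, r, alternative=alternative, method="asymptotic")
        p = float(p)
    return w, p


def fisher_one_tailed(table: Sequence[Sequence[int]]) -> float:
    """Upper-tail Fisher exact p on a 2x2 table: hypergeometric
    P(X >= a) with margins fixed."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must hold non-negative integers")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    return float(sps.fisher_exact(t, alternative="greater")[1])


def bray_curtis_matrix(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample rows:
    d(u, v) = 1 - 2*sum(min(u, v)) / (sum(u) + sum(v)).

    Rows with zero total are flagged: any pair of all-zero rows has an
    undefined (NaN) distance.
    """
    if isinstance(counts, pd.DataFrame):
        index = counts.index
        x = counts.to_numpy(dtype=float)
    else:
        x = np.asarray(counts, float)
        index = pd.RangeIndex(x.shape[0])
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    sums = x.sum(axis=1)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        denom = sums[i] + sums[i + 1 :]
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(denom > 0, 1.0 - 2.0 * shared / denom, np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return pd.DataFrame(d, index=index, columns=index)


def pcoa(distances: pd.DataFrame | np.ndarray, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, orders axes by descending
    eigenvalue; negative eigenvalues are dropped and variance fractions are
    taken over the positive eigenvalues only.
    """
    d = distances.to_numpy(dtype=float) if isinstance(distances, pd.DataFrame) else np.asarray(distances, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-12, 1e-10 * abs(eigvals[0])) if n else 0.0
    positive = eigvals > tol
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)[None, :]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        lam_kept = lam[:n_axes]
    else:
        lam_kept = lam
    variance = lam_kept / lam.sum() if lam.size else lam_kept
    return OrdinationResult(coords, variance, eigvals)


def habitat_scan(
    values: Sequence[float],
    labels: Sequence[str],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """One-vs-rest rank-sum scan across habitat/region groups.

    For each group: its samples' values against all others'. No multiplicity
    correction is applied. Groups whose complement is empty are skipped with
    a note.
    """
    v = np.asarray(values, float)
    lab = np.asarray(labels)
    if v.size != lab.size:
        raise ValueError("values and labels must align")
    groups = sorted(set(lab.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for g in groups:
        mask = lab == g
        n_g = int(mask.sum())
        if n_g == 0 or n_g == v.size:
            rows.append((g, n_g, np.nan, np.nan, "skipped: empty group or empty rest"))
            continue
        stat, p = rank_sum(v[mask], v[~mask], alternative=alternative)
        rows.append((g, n_g, stat, p, ""))
    return pd.DataFrame(rows, columns=["group", "n", "statistic", "p_value", "note"])


def correlation_scan(
    frame: pd.DataFrame, target: str, covariates: Sequence[str]
) -> pd.DataFrame:
    """Spearman of one target column against each covariate column."""
    rows = []
    for cov in covariates:
        res = spearman(frame[target].to_numpy(), frame[cov].to_numpy())
        rows.append((cov, res.rho, res.p_value, res.n))
    return pd.DataFrame(rows, columns=["covariate", "rho", "p_value", "n"])
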