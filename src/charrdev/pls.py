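"""Two-block partial least squares between head shape and univariate traits.

The first singular pair of the between-block covariance matrix gives
paired directions maximizing covariation; the reported statistic is the
Pearson correlation r of the paired scores.  Significance comes from
permuting the rows of one block; effect sizes are computed on the
Fisher-z-transformed correlation (so that pairwise two-sample comparisons
between cross types are on a common, variance-stabilized scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PLSResult",
    "two_block_pls",
    "pls_permutation",
    "compare_pls",
    "pls_leave_one_out",
]


@dataclass
class PLSResult:
    """First singular pair of a two-block PLS with optional permutation null."""

    loadings1: np.ndarray  # (p,), unit norm
    loadings2: np.ndarray  # (q,), unit norm
    singular_values: np.ndarray
    r: float
    scores1: np.ndarray
    scores2: np.ndarray
    label: str = ""
    r_perm: np.ndarray | None = None
    p: float | None = None
    z: float | None = None  # effect size on the Fisher-z scale
    z_se: float | None = None

    @property
    def has_null(self) -> bool:
        return self.r_perm is not None


def _center(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, float)
    if x.ndim != 2:
        raise ValueError(f"{name} must be 2-D (n x variables)")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmin(sd))
        raise ValueError(f"{name} has a constant column (index {j})")
    return x - x.mean(axis=0)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def two_block_pls(block1: np.ndarray, block2: np.ndarray, label: str = "") -> PLSResult:
    """First singular pair of cov(block1, block2) and the score correlation.

    The sign convention fixes the largest-magnitude element of the
    first-block loadings to be positive (both loading vectors flipped
    together, leaving the singular decomposition intact)."""
    x = _center(block1, "block1")
    y = _center(block2, "block2")
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("blocks must have the same number of rows")
    if n < 3:
        raise ValueError("need at least 3 observations")
    c = x.T @ y / (n - 1)
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    a, b = u[:, 0], vt[0]
    sign = np.sign(a[np.argmax(np.abs(a))]) or 1.0
    a, b = a * sign, b * sign
    s1 = x @ a
    s2 = y @ b
    return PLSResult(
        loadings1=a,
        loadings2=b,
        singular_values=s,
        r=_corr(s1, s2),
        scores1=s1,
        scores2=s2,
        label=label,
    )


def _perm_r(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Score correlations for each row permutation of y (batched SVD)."""
    n = x.shape[0]
    yp = y[idx]  # (B, n, q)
    c = np.einsum("np,bnq->bpq", x, yp) / (n - 1)
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    a = u[:, :, 0]  # (B, p)
    b = vt[:, 0, :]  # (B, q)
    s1 = np.einsum("np,bp->bn", x, a)
    s2 = np.einsum("bnq,bq->bn", yp, b)
    s1 = s1 - s1.mean(axis=1, keepdims=True)
    s2 = s2 - s2.mean(axis=1, keepdims=True)
    denom = np.sqrt((s1**2).sum(axis=1) * (s2**2).sum(axis=1))
    return np.where(denom > 0, (s1 * s2).sum(axis=1) / np.maximum(denom, 1e-300), 0.0)


def pls_permutation(
    result: PLSResult,
    block1: np.ndarray,
    block2: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PLSResult:
    """Permutation test and effect size for a two-block PLS.

    Rows of the second block are permuted; p is the proportion of
    permuted-or-observed r at least as large as the observed (so p >=
    1/(n_perm + 1)); the effect size is the standardized position of the
    observed Fisher-z(r) within the permutation distribution."""
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    x = _center(block1, "block1")
    y = _center(block2, "block2")
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    idx = np.empty((n_perm, n), dtype=int)
    for b in range(n_perm):
        idx[b] = rng.permutation(n)
    r_perm = _perm_r(x, y, idx)
    r_all = np.concatenate([[result.r], r_perm])
    p = float((r_all >= result.r - 1e-15).mean())
    zt = np.arctanh(np.clip(r_all, -1 + 1e-12, 1 - 1e-12))
    se = float(zt.std(ddof=1))
    z = float((zt[0] - zt.mean()) / se) if se > 0 else 0.0
    result.r_perm = r_perm
    result.p = p
    result.z = z
    result.z_se = se
    return result


def compare_pls(a: PLSResult, b: PLSResult) -> tuple[float, float]:
    """Two-sample comparison of PLS effect sizes.

    Effect sizes are already standardized against their own permutation
    nulls (unit SE each), so the pairwise statistic is their difference
    scaled by the pooled SE sqrt(2); p is two-sided normal."""
    if not (a.has_null and b.has_null):
        raise ValueError("both results need permutation nulls; run pls_permutation first")
    z12 = (a.z - b.z) / np.sqrt(2.0)
    p = float(2.0 * norm.sf(abs(z12)))
    return float(z12), p


def pls_leave_one_out(block1: np.ndarray, block2: np.ndarray) -> pd.DataFrame:
    """Leave-one-out sensitivity of the PLS correlation: r with each
    observation removed, flagging influential individuals."""
    x = np.asarray(block1, float)
    y = np.asarray(block2, float)
    n = x.shape[0]
    rows = []
    for i in range(n):
        keep = np.arange(n) != i
        res = two_block_pls(x[keep], y[keep])
        rows.append({"left_out": i, "r": res.r})
    df = pd.DataFrame(rows)
    df["delta_r"] = df["r"] - two_block_pls(x, y).r
    return df
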