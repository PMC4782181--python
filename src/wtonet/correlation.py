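"""Signed Spearman correlation of regulatory factors against all genes.

Builds the significance-thresholded matrix A = [a_iu]: a_iu is the Spearman
rank correlation between GRF i and gene u if its p-value is below alpha,
and 0 otherwise.  A is rectangular (GRFs x all genes); the GRF-GRF block is
symmetric with zero diagonal and is the input to the topological-overlap
computation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Raw Spearman correlations (GRFs x genes) with two-sided p-values."""

    grf_ids: list[str]
    gene_ids: list[str]
    rho: np.ndarray
    pvalue: np.ndarray
    n_samples: int


@dataclass
class SignedCorrelationMatrix:
    """Significance-thresholded signed correlations A.

    ``a[i, u]`` is rho(i, u) when significant at ``alpha_used`` else 0.
    ``gene_ids`` is a superset containing ``grf_ids``; the GRF-GRF block is
    symmetric with zero diagonal.
    """

    grf_ids: list[str]
    gene_ids: list[str]
    a: np.ndarray
    alpha_used: float

    @property
    def grf_columns(self) -> np.ndarray:
        """Column indices of the GRFs within ``gene_ids``."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in self.grf_ids], dtype=int)

    @property
    def grf_block(self) -> np.ndarray:
        """The symmetric GRF x GRF sub-matrix of A."""
        return self.a[:, self.grf_columns]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.a, index=self.grf_ids, columns=self.gene_ids)


def _rank_zscores(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks standardized so Z @ Z.T / n is the Spearman rho.

    Returns (Z, constant_mask); constant rows get all-zero scores.
    """
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1)
    constant = sd == 0
    sd[constant] = 1.0
    n = values.shape[1]
    z = ranks / (sd[:, None] * np.sqrt(n))
    z[constant] = 0.0
    return z, constant


def spearman_matrix(
    grf_expr: ExpressionMatrix,
    all_expr: ExpressionMatrix,
    pvalue_method: str = "t",
) -> CorrelationResult:
    """Spearman rank correlation of every GRF against every gene.

    Ties receive average ranks; p-values are two-sided.  The default method
    is the t-distribution approximation with n - 2 degrees of freedom on
    the rank correlation; ``pvalue_method="exact"`` enumerates permutations
    of the observed rank vector (feasible only for n_samples <= 9).
    Constant genes yield rho = 0 with p = 1 and are logged.
    """
    if grf_expr.sample_ids != all_expr.sample_ids:
        raise ValueError(
            "sample identifiers differ or are ordered differently between "
            "the GRF and the full expression matrix"
        )
    n = all_expr.n_samples
    if n < 5:
        raise ValueError(f"need at least 5 samples, got {n}")
    zg, const_g = _rank_zscores(grf_expr.values)
    za, const_a = _rank_zscores(all_expr.values)
    # z rows have unit norm, so the plain dot product is the Pearson
    # correlation of the ranks, i.e. Spearman's rho with average ranks.
    rho = np.clip(zg @ za.T, -1.0, 1.0)
    n_const = int(const_g.sum() + const_a.sum())
    if n_const:
        logger.warning("%d constant gene(s): rho set to 0, p to 1", n_const)
    if pvalue_method == "t":
        pval = _t_pvalues(rho, n)
    elif pvalue_method == "exact":
        pval = _exact_pvalues(grf_expr.values, all_expr.values, rho)
    else:
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    pval[const_g, :] = 1.0
    pval[:, const_a] = 1.0
    rho[const_g, :] = 0.0
    rho[:, const_a] = 0.0
    return CorrelationResult(
        grf_ids=grf_expr.gene_ids,
        gene_ids=all_expr.gene_ids,
        rho=rho,
        pvalue=pval,
        n_samples=n,
    )


def _t_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(rho) * np.sqrt((n - 2) / (1.0 - rho**2))
    t = np.where(np.abs(rho) >= 1.0, np.inf, t)
    return 2.0 * stats.t.sf(t, df=n - 2)


def _exact_pvalues(
    x_values: np.ndarray, y_values: np.ndarray, rho: np.ndarray
) -> np.ndarray:
    """Exact two-sided permutation p-values, conditional on observed ranks.

    Enumerates all n! pairings of the two rank vectors; O(n! * pairs), so
    gated to n <= 9.
    """
    n = x_values.shape[1]
    if n > 9:
        raise ValueError("exact Spearman p-values supported for n_samples <= 9 only")
    xr = stats.rankdata(x_values, axis=1)
    yr = stats.rankdata(y_values, axis=1)
    perms = np.array(list(itertools.permutations(range(n))))
    pval = np.empty_like(rho)
    for i in range(xr.shape[0]):
        xi = xr[i] - xr[i].mean()
        nx = np.sqrt((xi**2).sum())
        for j in range(yr.shape[0]):
            yj = yr[j] - yr[j].mean()
            ny = np.sqrt((yj**2).sum())
            if nx == 0 or ny == 0:
                pval[i, j] = 1.0
                continue
            null = (yj[perms] @ xi) / (nx * ny)
            obs = abs(xi @ yj) / (nx * ny)
            pval[i, j] = np.mean(np.abs(null) >= obs - 1e-12)
    return pval


def threshold_significant(
    corr: CorrelationResult, alpha: float = 0.05
) -> SignedCorrelationMatrix:
    """Zero out non-significant correlations (keep p < alpha strictly).

    The GRF-GRF diagonal is forced to zero (a_ii = 0) and the block is
    asserted symmetric — it is symmetric by construction when the GRF rows
    of both input matrices carry identical values.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    pos = {g: i for i, g in enumerate(corr.gene_ids)}
    missing = [g for g in corr.grf_ids if g not in pos]
    if missing:
        raise ValueError(f"GRFs absent from the gene universe: {missing}")
    a = np.where(corr.pvalue < alpha, corr.rho, 0.0)
    cols = np.array([pos[g] for g in corr.grf_ids], dtype=int)
    block = a[:, cols]
    if not np.allclose(block, block.T, atol=1e-10):
        raise ValueError(
            "GRF-GRF block is not symmetric; GRF rows must carry the same "
            "expression values in both input matrices"
        )
    a[np.arange(len(corr.grf_ids)), cols] = 0.0
    return SignedCorrelationMatrix(
        grf_ids=list(corr.grf_ids),
        gene_ids=list(corr.gene_ids),
        a=a,
        alpha_used=alpha,
    )


def dump_sparse(A: SignedCorrelationMatrix, corr: CorrelationResult, path) -> None:
    """Write non-zero entries of A as a triplet TSV (grf, gene, a, p)."""
    rows = []
    for i, g in enumerate(A.grf_ids):
        nz = np.nonzero(A.a[i])[0]
        for u in nz:
            rows.append((g, A.gene_ids[u], A.a[i, u], corr.pvalue[i, u]))
    df = pd.DataFrame(rows, columns=["grf_id", "gene_id", "a", "p"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
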