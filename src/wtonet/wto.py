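"""Signed weighted topological overlap (wTO) networks and their
permutation-null calibration.

For a pair of gene regulatory factors (i, j) with thresholded signed
correlation rows a_i*, a_j* of A:

    c_ij    = sum over u not in {i, j} of a_iu * a_ju      (shared-neighbor overlap)
    K_i     = sum over u != i of |a_iu|                    (weighted connectivity)
    omega_ij = (c_ij + a_ij) / (min(K_i, K_j) + 1 - |a_ij|)

The overlap index u ranges over either every gene in A ("all_genes") or the
GRFs only ("grf_only").  K uses absolute values so that |omega| <= 1 always
holds and the statistic reduces to the classical topological overlap for a
non-negative A; the sign of omega is positive when i and j correlate with
their shared neighborhood in the same direction and negative when they
correlate in opposite directions.

Calibration: the expression values are reshuffled independently within each
sample (each individual's values are reassigned to random genes), the whole
correlation + wTO pipeline is recomputed per permutation, and link counts at
a grid of |omega| cutoffs are compared between the real and the permuted
networks, giving an empirical p-value and a false positive rate per cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import SignedCorrelationMatrix, spearman_matrix, threshold_significant
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


@dataclass
class WTONetwork:
    """Symmetric GRF x GRF matrix of signed wTO values (zero diagonal)."""

    grf_ids: list[str]
    omega: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.omega
        if m.shape != (len(self.grf_ids), len(self.grf_ids)):
            raise ValueError("omega shape does not match grf_ids")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("omega must be symmetric")

    def link_count(self, cutoff: float) -> int:
        """Number of unordered pairs with |omega| strictly above ``cutoff``."""
        iu = np.triu_indices(len(self.grf_ids), k=1)
        return int((np.abs(self.omega[iu]) > cutoff).sum())

    def edges(self, cutoff: float = 0.0) -> pd.DataFrame:
        """Edge list (grf_a < grf_b lexicographically) with |omega| > cutoff."""
        ids = np.array(self.grf_ids)
        iu = np.triu_indices(len(ids), k=1)
        w = self.omega[iu]
        keep = np.abs(w) > cutoff
        a, b = ids[iu[0][keep]], ids[iu[1][keep]]
        swap = a > b
        a2 = np.where(swap, b, a)
        b2 = np.where(swap, a, b)
        df = pd.DataFrame({"grf_a": a2, "grf_b": b2, "wto": w[keep]})
        return df.sort_values(["grf_a", "grf_b"], ignore_index=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.omega, index=self.grf_ids, columns=self.grf_ids)


def compute_wto(
    A: SignedCorrelationMatrix, overlap_set: str = "all_genes"
) -> WTONetwork:
    """Signed weighted topological overlap for every GRF pair in A.

    ``overlap_set="all_genes"`` sums the shared neighborhood over every gene
    column of A; ``"grf_only"`` restricts it to the GRF columns.  Because
    a_ii = 0 in the GRF block, the u = i and u = j terms vanish from the
    matrix product, so C = S S^T realises the excluded sum directly.
    """
    if overlap_set not in {"all_genes", "grf_only"}:
        raise ValueError(f"unknown overlap_set {overlap_set!r}")
    if not np.isfinite(A.a).all():
        raise ValueError("correlation matrix contains non-finite values")
    block = A.grf_block
    S = A.a if overlap_set == "all_genes" else block
    C = S @ S.T
    K = np.abs(S).sum(axis=1)
    num = C + block
    den = np.minimum.outer(K, K) + 1.0 - np.abs(block)
    # K_i >= |a_ij| always, so den >= 1; no division guard needed.
    omega = num / den
    np.fill_diagonal(omega, 0.0)
    omega = np.clip(omega, -1.0, 1.0)
    return WTONetwork(
        grf_ids=list(A.grf_ids),
        omega=omega,
        provenance={"alpha": A.alpha_used, "overlap_set": overlap_set},
    )


def wto_brute_force(
    A: SignedCorrelationMatrix, overlap_set: str = "all_genes"
) -> np.ndarray:
    """Reference implementation: explicit sum over u for every pair.

    Kept deliberately loop-based as an independent oracle for the
    matrix-product implementation.
    """
    block = A.grf_block
    S = A.a if overlap_set == "all_genes" else block
    cols = (
        A.grf_columns
        if overlap_set == "all_genes"
        else np.arange(len(A.grf_ids))
    )
    n = len(A.grf_ids)
    n_u = S.shape[1]
    omega = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            c = 0.0
            for u in range(n_u):
                if u == cols[i] or u == cols[j]:
                    continue
                c += S[i, u] * S[j, u]
            ki = sum(abs(S[i, u]) for u in range(n_u) if u != cols[i])
            kj = sum(abs(S[j, u]) for u in range(n_u) if u != cols[j])
            a_ij = block[i, j]
            omega[i, j] = (c + a_ij) / (min(ki, kj) + 1.0 - abs(a_ij))
    return omega


def wto_from_expression(
    mat: ExpressionMatrix,
    grf_ids,
    alpha: float = 0.05,
    overlap_set: str = "all_genes",
    dataset_tag: str = "",
) -> WTONetwork:
    """Full single-dataset pipeline: Spearman -> threshold -> wTO."""
    present = [g for g in grf_ids if g in mat.data.index]
    if len(present) < 2:
        raise ValueError("fewer than two GRFs present in the expression matrix")
    corr = spearman_matrix(mat.subset(present), mat)
    A = threshold_significant(corr, alpha=alpha)
    net = compute_wto(A, overlap_set=overlap_set)
    net.provenance["dataset"] = dataset_tag
    return net


def permute_expression(mat: ExpressionMatrix, rng: np.random.Generator) -> ExpressionMatrix:
    """Reshuffle expression values across genes, independently per sample.

    Each column's value multiset is preserved exactly; only the assignment
    of values to gene labels is randomized, separately for each individual.
    """
    values = mat.values.copy()
    n_genes, n_samples = values.shape
    for s in range(n_samples):
        values[:, s] = values[rng.permutation(n_genes), s]
    return ExpressionMatrix(
        pd.DataFrame(values, index=mat.gene_ids, columns=mat.sample_ids),
        mat.platform_tag,
    )


@dataclass
class NullCalibration:
    """Per-cutoff comparison of real vs permuted link counts.

    ``empirical_p`` uses the add-one pseudocount (never exactly zero) and
    counts ties against significance; ``fpr`` is mean permuted count over
    real count, NaN where the real network has no links at that cutoff.
    """

    cutoffs: np.ndarray
    real_counts: np.ndarray
    perm_counts: np.ndarray  # n_perm x n_cutoffs
    empirical_p: np.ndarray
    fpr: np.ndarray
    n_perm: int
    seed: int

    @property
    def recommended_cutoff(self) -> float | None:
        """Smallest cutoff whose empirical p is below 0.01, if any."""
        ok = np.nonzero(self.empirical_p < 0.01)[0]
        return float(self.cutoffs[ok[0]]) if ok.size else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "real": self.real_counts,
                "perm_mean": self.perm_counts.mean(axis=0),
                "perm_max": self.perm_counts.max(axis=0),
                "empirical_p": self.empirical_p,
                "fpr": self.fpr,
            }
        )


def calibrate_null(
    mat: ExpressionMatrix,
    grf_ids,
    n_perm: int = 100,
    cutoffs=DEFAULT_CUTOFFS,
    alpha: float = 0.05,
    overlap_set: str = "all_genes",
    seed: int = 0,
) -> NullCalibration:
    """Compare real link counts against per-individual permutation nulls.

    Builds the real wTO network once and one network per permuted matrix,
    counting links with |omega| > cutoff over a strictly increasing grid.
    empirical_p(cutoff) = (1 + #{perm count >= real count}) / (1 + n_perm).
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (np.all(np.diff(cutoffs) > 0) and np.all((cutoffs > 0) & (cutoffs < 1))):
        raise ValueError("cutoffs must be strictly increasing and lie in (0, 1)")
    real = wto_from_expression(mat, grf_ids, alpha=alpha, overlap_set=overlap_set)
    real_counts = np.array([real.link_count(c) for c in cutoffs])
    perm_counts = np.zeros((n_perm, len(cutoffs)), dtype=int)
    for p in range(n_perm):
        # independent substream per permutation: reproducible and
        # order-independent
        rng = np.random.default_rng([seed, p])
        permuted = permute_expression(mat, rng)
        net = wto_from_expression(
            permuted, grf_ids, alpha=alpha, overlap_set=overlap_set
        )
        perm_counts[p] = [net.link_count(c) for c in cutoffs]
    ge = (perm_counts >= real_counts[None, :]).sum(axis=0)
    empirical_p = (1.0 + ge) / (1.0 + n_perm)
    with np.errstate(divide="ignore", invalid="ignore"):
        fpr = np.where(
            real_counts > 0, perm_counts.mean(axis=0) / real_counts, np.nan
        )
    if (real_counts == 0).any():
        logger.info(
            "no real links at cutoffs %s; FPR marked unavailable",
            cutoffs[real_counts == 0],
        )
    return NullCalibration(
        cutoffs=cutoffs,
        real_counts=real_counts,
        perm_counts=perm_counts,
        empirical_p=empirical_p,
        fpr=fpr,
        n_perm=n_perm,
        seed=seed,
    )
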