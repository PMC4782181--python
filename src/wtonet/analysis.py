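"""Downstream network analytics: hubs, group connectivity, gene-set
overlap enrichment, and cross-dataset variability summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consensus import ConsensusNetwork, WTOStack
from .wto import WTONetwork

HUB_DEGREE_FLOOR = 25


def degrees(net: ConsensusNetwork | WTONetwork, cutoff: float | None = None) -> pd.Series:
    """Per-GRF link counts, sign-blind (negative links count too).

    For a raw wTO network a ``cutoff`` on |omega| is required; a consensus
    network is already thresholded.  Nodes without links are included with
    degree 0 (for a consensus network, only nodes carrying links are known).
    """
    if isinstance(net, ConsensusNetwork):
        edges = net.links[["grf_a", "grf_b"]]
        nodes = net.node_ids
    elif isinstance(net, WTONetwork):
        if cutoff is None:
            raise ValueError("a |wTO| cutoff is required for a raw wTO network")
        edges = net.edges(cutoff)[["grf_a", "grf_b"]]
        nodes = sorted(net.grf_ids)
    else:
        raise TypeError(f"unsupported network type {type(net).__name__}")
    counts = pd.concat([edges["grf_a"], edges["grf_b"]]).value_counts()
    deg = counts.reindex(nodes, fill_value=0).astype(int)
    deg.index.name = "gene_id"
    deg.name = "degree"
    return deg.sort_index()


def hubs(deg: pd.Series, min_degree: int = HUB_DEGREE_FLOOR) -> list[str]:
    """Nodes with degree strictly greater than ``min_degree``."""
    return sorted(deg.index[deg > min_degree])


def compare_connectivity(deg: pd.Series, group_a: Iterable, group_b: Iterable) -> float:
    """One-sided unpaired rank-sum p for group_a being more connected.

    Tests the alternative that group_a's degrees are stochastically greater
    than group_b's (Wilcoxon rank-sum / Mann-Whitney U, unpaired).
    """
    a, b = set(group_a), set(group_b)
    if a & b:
        raise ValueError(f"groups overlap: {sorted(a & b)}")
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    missing = sorted((a | b) - set(deg.index))
    if missing:
        raise ValueError(f"group members absent from the network: {missing}")
    res = stats.mannwhitneyu(
        deg.loc[sorted(a)], deg.loc[sorted(b)], alternative="greater"
    )
    return float(res.pvalue)


@dataclass
class EnrichmentResult:
    """Overlap of two gene sets against a common background universe."""

    overlap_k: int
    set_a_size: int
    set_b_size: int
    background_size: int
    p_hyper: float
    odds_ratio: float
    p_perm_external: float = float("nan")
    p_perm_internal: float = float("nan")
    p_adjusted: float = float("nan")
    overlap_genes: list = field(default_factory=list)


def overlap_enrichment(
    set_a: Iterable,
    set_b: Iterable,
    background: Iterable,
    n_perm: int = 1000,
    internal_pool: Iterable | None = None,
    seed: int | None = None,
) -> EnrichmentResult:
    """Hypergeometric overlap test with two-way permutation validation.

    ``p_hyper`` is the upper tail P(X >= k) for drawing |set_a| genes from
    the background containing |set_b| successes (equal to the one-sided
    Fisher exact p of the 2x2 table).  The external permutation resamples
    set_b uniformly from the background; the internal permutation resamples
    set_a from ``internal_pool`` (an expressed subset; defaults to the
    background).  Both permutation p-values use the add-one pseudocount.
    The odds ratio is the sample cross-product ratio with a Haldane 0.5
    correction when a table cell is zero.
    """
    bg = sorted(set(background))
    a, b = set(set_a), set(set_b)
    offenders = sorted((a | b) - set(bg))
    if offenders:
        raise ValueError(f"set members outside the background: {offenders}")
    N, na, nb = len(bg), len(a), len(b)
    k = len(a & b)
    p_hyper = float(stats.hypergeom.sf(k - 1, N, nb, na))
    t11, t12, t21 = k, na - k, nb - k
    t22 = N - na - nb + k
    if min(t11, t12, t21, t22) == 0:
        t11, t12, t21, t22 = (t + 0.5 for t in (t11, t12, t21, t22))
    odds_ratio = (t11 * t22) / (t12 * t21)
    p_ext = p_int = float("nan")
    if n_perm:
        rng = np.random.default_rng(seed)
        in_a = np.isin(np.array(bg), sorted(a))
        hits_ext = sum(
            int(in_a[rng.choice(N, size=nb, replace=False)].sum() >= k)
            for _ in range(n_perm)
        )
        p_ext = (1.0 + hits_ext) / (1.0 + n_perm)
        pool = sorted(set(internal_pool)) if internal_pool is not None else bg
        bad = sorted(set(pool) - set(bg))
        if bad:
            raise ValueError(f"internal pool members outside the background: {bad}")
        in_b = np.isin(np.array(pool), sorted(b))
        if na > len(pool):
            raise ValueError("internal pool smaller than set_a")
        hits_int = sum(
            int(in_b[rng.choice(len(pool), size=na, replace=False)].sum() >= k)
            for _ in range(n_perm)
        )
        p_int = (1.0 + hits_int) / (1.0 + n_perm)
    return EnrichmentResult(
        overlap_k=k,
        set_a_size=na,
        set_b_size=nb,
        background_size=N,
        p_hyper=p_hyper,
        odds_ratio=float(odds_ratio),
        p_perm_external=p_ext,
        p_perm_internal=p_int,
        overlap_genes=sorted(a & b),
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_batch(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Fill ``p_adjusted`` across a batch of enrichment results (BH)."""
    adj = benjamini_hochberg([r.p_hyper for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results


def _fivenum(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """Tukey five-number summary (hinges), the boxplot-statistics convention."""
    v = np.sort(np.asarray(x, dtype=float))
    n = v.size
    n4 = np.floor((n + 3) / 2) / 2
    d = np.array([1.0, n4, (n + 1) / 2, n + 1 - n4, float(n)])
    lo = v[np.floor(d).astype(int) - 1]
    hi = v[np.ceil(d).astype(int) - 1]
    return tuple(0.5 * (lo + hi))


@dataclass
class OutlierResult:
    outliers: np.ndarray
    count: int
    lower_fence: float
    upper_fence: float
    q1: float
    median: float
    q3: float


def wto_outliers(values) -> OutlierResult:
    """Tukey-fence outliers of one dataset's omega values.

    Quartiles are boxplot hinges; outliers fall below Q1 - 1.5*IQR or above
    Q3 + 1.5*IQR.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least four values")
    _, q1, med, q3, _ = _fivenum(v)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    out = v[(v < lo) | (v > hi)]
    return OutlierResult(
        outliers=out, count=int(out.size),
        lower_fence=float(lo), upper_fence=float(hi),
        q1=float(q1), median=float(med), q3=float(q3),
    )


@dataclass
class DatasetComparison:
    """Cross-dataset variability: boxplot summaries, distances, 2-D map."""

    summaries: pd.DataFrame
    distances: pd.DataFrame
    coordinates: pd.DataFrame


def classical_mds(distances: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric scaling via double-centering.

    Coordinates are defined up to rotation/reflection; negative eigenvalues
    (non-Euclidean residual) are truncated at zero.
    """
    D = np.asarray(distances, dtype=float)
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:n_components]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def dataset_scaling(stack: WTOStack) -> DatasetComparison:
    """Summarize and embed the datasets of a wTO stack.

    Pairwise dataset distance is the Euclidean distance over the GRF pairs
    defined in both datasets (pairwise-complete); the 2-D embedding is
    classical metric scaling of that distance matrix.  Per-dataset
    summaries report hinge quartiles, Tukey fences, and outlier counts of
    the omega distribution.
    """
    if stack.n_datasets < 3:
        raise ValueError("need at least three datasets")
    tags = stack.dataset_ids
    V = stack.values
    m = len(tags)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            both = V.iloc[:, [i, j]].dropna()
            if both.empty:
                raise ValueError(
                    f"datasets {tags[i]!r} and {tags[j]!r} share no defined pairs"
                )
            diff = both.iloc[:, 0] - both.iloc[:, 1]
            D[i, j] = D[j, i] = float(np.sqrt((diff**2).sum()))
    rows = []
    for tag in tags:
        vals = V[tag].dropna().to_numpy()
        if vals.size >= 4:
            res = wto_outliers(vals)
            rows.append(
                {
                    "dataset": tag, "n_pairs": vals.size,
                    "q1": res.q1, "median": res.median, "q3": res.q3,
                    "lower_fence": res.lower_fence, "upper_fence": res.upper_fence,
                    "n_outliers": res.count,
                }
            )
        else:  # too few pairs for boxplot statistics
            rows.append(
                {
                    "dataset": tag, "n_pairs": vals.size,
                    "q1": np.nan, "median": float(np.median(vals)) if vals.size else np.nan,
                    "q3": np.nan, "lower_fence": np.nan, "upper_fence": np.nan,
                    "n_outliers": 0,
                }
            )
    coords = classical_mds(D, n_components=2)
    return DatasetComparison(
        summaries=pd.DataFrame(rows).set_index("dataset"),
        distances=pd.DataFrame(D, index=tags, columns=tags),
        coordinates=pd.DataFrame(coords, index=tags, columns=["dim1", "dim2"]),
    )
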