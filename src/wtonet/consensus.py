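"""Consensus integration of independently derived wTO networks.

The per-dataset networks are treated as biological replicates.  For every
GRF pair present in enough datasets, the distribution of |omega| values
across datasets is tested against a fixed location (one-sample Wilcoxon
signed-rank, alternative "greater", default mu = 0.3); pairs passing at
alpha enter the consensus with the median of their signed omega values as
consensus weight.  Requiring the whole distribution to sit above the cutoff
discards pairs whose strength varies wildly across datasets, which is the
point: a single extreme dataset cannot create a consensus link.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .wto import WTONetwork

logger = logging.getLogger(__name__)


@dataclass
class WTOStack:
    """GRF pairs x datasets matrix of omega values.

    ``values`` is indexed by canonical pairs (grf_a < grf_b, lexicographic)
    with one column per dataset; NaN marks a pair undefined in a dataset
    (a member GRF absent there).
    """

    values: pd.DataFrame

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_datasets(self) -> int:
        return self.values.shape[1]

    @property
    def pair_ids(self) -> list[tuple[str, str]]:
        return list(self.values.index)


def align_networks(nets: list[WTONetwork], dataset_ids=None) -> WTOStack:
    """Stack per-dataset networks over the union of their GRF pairs.

    A pair is defined in a dataset iff both GRFs are present there; its
    omega value (including exact zeros) is recorded, otherwise NaN.
    """
    if len(nets) < 2:
        raise ValueError("need at least two networks to align")
    if dataset_ids is None:
        dataset_ids = [
            net.provenance.get("dataset") or f"ds{i}" for i, net in enumerate(nets)
        ]
    if len(set(dataset_ids)) != len(nets):
        raise ValueError("dataset_ids must be unique, one per network")
    columns = {}
    for tag, net in zip(dataset_ids, nets):
        ids = np.array(net.grf_ids)
        iu = np.triu_indices(len(ids), k=1)
        a, b = ids[iu[0]], ids[iu[1]]
        swap = a > b
        pairs = list(zip(np.where(swap, b, a), np.where(swap, a, b)))
        columns[tag] = pd.Series(net.omega[iu], index=pd.MultiIndex.from_tuples(pairs))
    values = pd.DataFrame(columns).sort_index()
    values.index.names = ["grf_a", "grf_b"]
    return WTOStack(values=values)


def _exact_signflip_pvalue(d: np.ndarray) -> float:
    """Exact one-sided signed-rank p by enumerating the sign-flip null.

    Conditional on the observed |d| (average ranks, so tied magnitudes are
    handled exactly), every one of the 2^n sign assignments is equally
    likely under H0.  Ranks are doubled to integers and the distribution of
    W+ = sum of positive ranks is built by dynamic programming, so the cost
    is O(n^3) rather than O(2^n).
    """
    ranks2 = np.round(2.0 * stats.rankdata(np.abs(d))).astype(int)
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w_obs = int(ranks2[d > 0].sum())
    return float(counts[w_obs:].sum() / 2.0 ** len(d))


def wilcoxon_greater_than_mu(values, mu: float = 0.3) -> float:
    """One-sample Wilcoxon signed-rank p for location > mu.

    Zero differences are dropped before ranking; if every difference is
    zero the test carries no evidence and p = 1.  The null distribution is
    exact (sign-flip enumeration, ties supported) up to n = 25, beyond that
    a normal approximation with tie-corrected variance is used.
    Differences are rounded to 12 decimals first so that equal spacings do
    not acquire artificial rank order from floating-point representation.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    d = np.round(values - mu, 12)
    d = d[d != 0]
    if d.size == 0:
        logger.info("all differences zero at mu=%g; p = 1", mu)
        return 1.0
    if d.size <= 25:
        return _exact_signflip_pvalue(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(d, alternative="greater", method="approx")
    return float(res.pvalue)


@dataclass
class ConsensusNetwork:
    """Statistically supported links with median consensus weights.

    ``links`` columns: grf_a, grf_b, median_wto, p_value, n_present,
    sign_consistent (True iff every defined omega shares one strict sign).
    """

    links: pd.DataFrame
    threshold_used: float
    alpha_used: float

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def node_ids(self) -> list[str]:
        return sorted(set(self.links["grf_a"]) | set(self.links["grf_b"]))


def build_consensus(
    stack: WTOStack,
    threshold: float = 0.3,
    alpha: float = 0.05,
    min_present: int | None = None,
) -> ConsensusNetwork:
    """Test every sufficiently observed pair and keep the significant ones.

    For each pair with at least ``min_present`` defined omega values
    (default: present in every dataset of the stack), the |omega| sample is
    tested for location above ``threshold``; if p < alpha the pair becomes
    a link weighted by the median of its signed omega values.  Note the
    exact signed-rank test cannot reach p < 0.05 below n = 5, so small
    ``min_present`` values silently admit no links.
    """
    if min_present is None:
        min_present = stack.n_datasets
    if min_present < 2:
        raise ValueError("min_present must be >= 2")
    rows = []
    for pair, row in stack.values.iterrows():
        vals = row.dropna().to_numpy()
        if vals.size < min_present:
            continue
        p = wilcoxon_greater_than_mu(np.abs(vals), mu=threshold)
        if p < alpha:
            rows.append(
                {
                    "grf_a": pair[0],
                    "grf_b": pair[1],
                    "median_wto": float(np.median(vals)),
                    "p_value": p,
                    "n_present": int(vals.size),
                    "sign_consistent": bool((vals > 0).all() or (vals < 0).all()),
                }
            )
    links = pd.DataFrame(
        rows,
        columns=[
            "grf_a", "grf_b", "median_wto", "p_value", "n_present",
            "sign_consistent",
        ],
    )
    links = links.sort_values(["grf_a", "grf_b"], ignore_index=True)
    n_mixed = int((~links["sign_consistent"]).sum()) if len(links) else 0
    if n_mixed:
        logger.info("%d consensus link(s) have mixed signs across datasets", n_mixed)
    return ConsensusNetwork(links=links, threshold_used=threshold, alpha_used=alpha)


def mean_calibrated_cutoff(calibrations) -> float:
    """Mean of the per-dataset recommended cutoffs (empirical p < 0.01).

    This is how the default consensus threshold can be derived from the
    permutation calibration of the individual networks instead of being
    fixed a priori.
    """
    cuts = [c.recommended_cutoff for c in calibrations]
    missing = [i for i, c in enumerate(cuts) if c is None]
    if missing:
        raise ValueError(
            f"calibration(s) {missing} have no cutoff with empirical p < 0.01"
        )
    return float(np.mean(cuts))
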