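"""Loading and filtering of gene-expression matrices.

The unit of work is a genes x samples matrix of RPKM values (RNA-seq) or
summarized log-intensities (microarray) with unique row and column
identifiers.  Filtering rules:

* RPKM filter — keep genes expressed above a floor in a large fraction of
  samples (default: value > 0.5 in at least ceil(0.9 * n_samples) samples).
* Detection filter — keep probes whose detection p-value is significant in
  at least one individual (default p < 0.05).
* Probeset collapse — genes represented by several probesets are collapsed
  to the per-sample arithmetic mean of their probes.

Matrices must be complete: missing entries are a hard error by default,
optionally the whole gene row is dropped.  Values are never imputed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RNASEQ = "rnaseq"
MICROARRAY = "microarray"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  Must be complete (no NaN) and numeric.
    platform_tag
        ``"rnaseq"`` for RPKM-like matrices (must be non-negative) or
        ``"microarray"`` for intensity-like matrices.
    """

    data: pd.DataFrame
    platform_tag: str = RNASEQ

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        dup = idx[idx.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate gene identifiers: {dup}")
        dup = cols[cols.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate sample identifiers: {dup}")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric expression values: {exc}") from exc
        if self.data.isna().any().any():
            bad = self.data.isna()
            gene = bad.any(axis=1).idxmax()
            sample = bad.loc[gene].idxmax()
            raise ValueError(
                f"missing value at gene {gene!r}, sample {sample!r}; "
                "matrices must be complete (drop or fix upstream)"
            )
        if self.platform_tag == RNASEQ and (self.data.values < 0).any():
            raise ValueError("RPKM-tagged matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(self, gene_ids) -> "ExpressionMatrix":
        """Row-subset preserving the requested order."""
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"gene identifiers not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.platform_tag)


@dataclass
class DetectionMatrix:
    """Probe-level detection p-values matched to a probe expression matrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("detection matrix contains missing values")
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("detection p-values must lie in [0, 1]")


def read_expression(
    path: str | Path,
    delimiter: str = "\t",
    platform_tag: str = RNASEQ,
    missing: str = "error",
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix.

    First column holds gene identifiers, header row holds sample identifiers.

    Parameters
    ----------
    missing
        ``"error"`` (default) — any empty/NA cell raises naming its
        coordinate; ``"drop"`` — rows containing missing values are dropped
        and the count logged.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty expression file: {path}") from exc
    if raw.shape[1] == 0:
        raise ValueError(f"no sample columns found in {path}")
    missing_mask = raw.isna()
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~missing_mask
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        sample = bad.loc[gene].idxmax()
        raise ValueError(
            f"non-numeric value {raw.loc[gene, sample]!r} at "
            f"gene {gene!r}, sample {sample!r} in {path}"
        )
    if missing_mask.any().any():
        if missing == "drop":
            n_before = numeric.shape[0]
            numeric = numeric.loc[~missing_mask.any(axis=1)]
            logger.warning(
                "dropped %d gene rows with missing values from %s",
                n_before - numeric.shape[0], path,
            )
        else:
            gene = missing_mask.any(axis=1).idxmax()
            sample = missing_mask.loc[gene].idxmax()
            raise ValueError(
                f"missing value at gene {gene!r}, sample {sample!r} in {path} "
                "(pass missing='drop' to discard such rows)"
            )
    dup = numeric.index[numeric.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene identifiers in {path}: {dup}")
    return ExpressionMatrix(numeric, platform_tag)


def read_detection(path: str | Path, delimiter: str = "\t") -> DetectionMatrix:
    """Read a probe x sample detection-p-value matrix."""
    try:
        raw = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty detection file: {path}") from exc
    return DetectionMatrix(raw)


def filter_rpkm(
    mat: ExpressionMatrix,
    min_value: float = 0.5,
    min_fraction: float = 0.9,
) -> ExpressionMatrix:
    """Keep genes with value strictly > ``min_value`` in at least
    ``ceil(min_fraction * n_samples)`` samples.

    Sample set and order are unchanged; retained values are untouched.
    """
    if mat.platform_tag != RNASEQ:
        raise ValueError("RPKM filter applies to RPKM-tagged matrices only")
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must lie in (0, 1], got {min_fraction}")
    need = math.ceil(min_fraction * mat.n_samples)
    counts = (mat.values > min_value).sum(axis=1)
    keep = counts >= need
    if not keep.any():
        warnings.warn("RPKM filter removed every gene", stacklevel=2)
    return ExpressionMatrix(mat.data.loc[keep], mat.platform_tag)


def filter_detection(
    probe_mat: ExpressionMatrix,
    det: DetectionMatrix,
    alpha: float = 0.05,
) -> ExpressionMatrix:
    """Keep probes significantly detected (p < alpha) in at least one sample."""
    if set(det.data.index) != set(probe_mat.gene_ids) or set(
        det.data.columns
    ) != set(probe_mat.sample_ids):
        extra = sorted(set(det.data.index) ^ set(probe_mat.gene_ids))
        extra += sorted(set(det.data.columns) ^ set(probe_mat.sample_ids))
        raise ValueError(f"detection matrix misaligned; mismatched ids: {extra}")
    aligned = det.data.loc[probe_mat.gene_ids, probe_mat.sample_ids]
    keep = (aligned.to_numpy() < alpha).any(axis=1)
    if not keep.any():
        warnings.warn("detection filter removed every probe", stacklevel=2)
    return ExpressionMatrix(probe_mat.data.loc[keep], probe_mat.platform_tag)


def collapse_probesets(
    probe_mat: ExpressionMatrix,
    probe_to_gene: Mapping[str, str],
    on_unmapped: str = "drop",
) -> ExpressionMatrix:
    """Collapse probe rows to gene rows by per-sample arithmetic mean.

    Genes appear in order of their first probe.  Probes without a mapping
    are dropped with a logged count, or raise if ``on_unmapped="error"``.
    """
    unmapped = [p for p in probe_mat.gene_ids if p not in probe_to_gene]
    if unmapped:
        if on_unmapped == "error":
            raise ValueError(f"probes without gene mapping: {unmapped}")
        logger.warning("dropping %d unmapped probes", len(unmapped))
    mapped = probe_mat.data.loc[[p for p in probe_mat.gene_ids if p in probe_to_gene]]
    genes = mapped.index.map(probe_to_gene.__getitem__)
    collapsed = mapped.groupby(genes, sort=False).mean()
    collapsed.index.name = probe_mat.data.index.name
    return ExpressionMatrix(collapsed, probe_mat.platform_tag)


def read_annotation(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a node-annotation table (gene_id, is_grf, is_brain_grf, label).

    Returns a DataFrame indexed by gene_id with boolean is_grf/is_brain_grf
    columns.  Being a Brain-GRF implies being a GRF.
    """
    ann = pd.read_csv(path, sep=delimiter, dtype={"gene_id": str})
    required = {"gene_id", "is_grf", "is_brain_grf"}
    missing_cols = required - set(ann.columns)
    if missing_cols:
        raise ValueError(f"annotation missing columns: {sorted(missing_cols)}")
    dup = ann["gene_id"][ann["gene_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene_id in annotation: {dup}")
    ann = ann.set_index("gene_id")
    for col in ("is_grf", "is_brain_grf"):
        ann[col] = ann[col].map(_to_bool)
    bad = ann.index[ann["is_brain_grf"] & ~ann["is_grf"]].tolist()
    if bad:
        raise ValueError(f"is_brain_grf set without is_grf for: {bad}")
    if "label" not in ann.columns:
        ann["label"] = ""
    return ann


def _to_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    raise ValueError(f"cannot interpret {x!r} as boolean")
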