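"""Synthetic multi-dataset expression data with planted GRF co-regulation.

A one-latent-factor-per-module linear model: each module m has a latent
activity z_m drawn independently per sample; a member gene g (GRF or
target) expresses beta * sign_g * z_m plus Gaussian noise.  Genes outside
every module are pure noise.  Independent datasets are fresh draws of the
same structure — biological replicates — so the planted within-module GRF
pairs are exactly the links a consensus over the datasets should recover,
with sign equal to the product of the member loading signs.

Values are shifted by a positive baseline so the matrices are valid
RPKM-like input for the expression filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import RNASEQ, ExpressionMatrix


@dataclass
class ModuleSpec:
    """One co-regulated module: member GRFs, loading signs, strength beta."""

    grf_ids: list[str]
    signs: list[int]
    strength: float = 0.85

    def __post_init__(self) -> None:
        if len(self.grf_ids) != len(self.signs):
            raise ValueError("one sign per member GRF required")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")
        if not 0 < self.strength < 1:
            raise ValueError("module strength must lie in (0, 1)")


@dataclass
class SyntheticConfig:
    """Study-condition defaults: 10 replicate datasets of 20 samples, two
    planted modules of 5 GRFs each (one negative loading in the second
    module), beta = 0.85, noise sd = 0.4, 200 target genes."""

    seed: int
    n_datasets: int = 10
    samples_per_dataset: list[int] | None = None
    n_grfs: int = 20
    n_targets: int = 200
    modules: list[ModuleSpec] | None = None
    noise_sd: float = 0.4
    baseline: float = 10.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.samples_per_dataset is None:
            self.samples_per_dataset = [20] * self.n_datasets
        if len(self.samples_per_dataset) != self.n_datasets:
            raise ValueError("one sample count per dataset required")
        if self.modules is None:
            if self.n_grfs < 10:
                raise ValueError(
                    "the default layout plants two modules of 5 GRFs and "
                    "needs n_grfs >= 10; pass explicit modules for smaller "
                    "catalogs"
                )
            ids = self.grf_ids
            self.modules = [
                ModuleSpec(ids[0:5], [1, 1, 1, 1, 1]),
                ModuleSpec(ids[5:10], [1, 1, 1, 1, -1]),
            ]
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        members = [g for m in self.modules for g in m.grf_ids]
        if len(set(members)) != len(members):
            raise ValueError("modules must be disjoint over GRFs")
        unknown = sorted(set(members) - set(self.grf_ids))
        if unknown:
            raise ValueError(f"module GRFs outside the GRF catalog: {unknown}")

    @property
    def grf_ids(self) -> list[str]:
        return [f"GRF{i + 1:03d}" for i in range(self.n_grfs)]

    @property
    def target_ids(self) -> list[str]:
        return [f"T{i + 1:03d}" for i in range(self.n_targets)]


@dataclass
class GroundTruth:
    """Expected consensus links: all within-module GRF pairs with sign =
    product of the member loading signs; every other pair is null."""

    links: pd.DataFrame  # columns grf_a, grf_b, sign
    target_module: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def link_set(self) -> set[tuple[str, str]]:
        return set(zip(self.links["grf_a"], self.links["grf_b"]))


def expected_link_set(cfg: SyntheticConfig) -> GroundTruth:
    """Enumerate the planted GRF-GRF links implied by the module layout."""
    rows = []
    for mod in cfg.modules:
        sign = dict(zip(mod.grf_ids, mod.signs))
        for g1, g2 in combinations(sorted(mod.grf_ids), 2):
            rows.append({"grf_a": g1, "grf_b": g2, "sign": sign[g1] * sign[g2]})
    links = pd.DataFrame(rows, columns=["grf_a", "grf_b", "sign"])
    return GroundTruth(links=links.sort_values(["grf_a", "grf_b"], ignore_index=True))


def generate_multiset(cfg: SyntheticConfig) -> tuple[list[ExpressionMatrix], GroundTruth]:
    """Draw the D independent datasets and their ground truth.

    Target genes are assigned round-robin to modules with a random loading
    sign each; assignments are fixed across datasets (the structure is the
    replicated object, the samples are the noise).  Same seed, same bytes.
    """
    master = np.random.default_rng(cfg.seed)
    n_modules = len(cfg.modules)
    assignment = []
    if n_modules and cfg.n_targets:
        for t, tid in enumerate(cfg.target_ids):
            assignment.append(
                (tid, t % n_modules, int(master.choice([-1, 1])))
            )
    target_module = pd.DataFrame(assignment, columns=["gene_id", "module", "sign"])
    gene_ids = cfg.grf_ids + cfg.target_ids
    grf_pos = {g: i for i, g in enumerate(cfg.grf_ids)}
    datasets = []
    for d in range(cfg.n_datasets):
        rng = np.random.default_rng([cfg.seed, d])
        n_s = cfg.samples_per_dataset[d]
        z = rng.standard_normal((n_modules, n_s))
        values = rng.normal(0.0, cfg.noise_sd, size=(len(gene_ids), n_s))
        for m, mod in enumerate(cfg.modules):
            for g, s in zip(mod.grf_ids, mod.signs):
                values[grf_pos[g]] += mod.strength * s * z[m]
        for _, row in target_module.iterrows():
            idx = cfg.n_grfs + int(row["gene_id"][1:]) - 1
            beta = cfg.modules[row["module"]].strength
            values[idx] += beta * row["sign"] * z[row["module"]]
        values += cfg.baseline
        if (values < 0).any():
            values = np.clip(values, 0.0, None)
        df = pd.DataFrame(
            values,
            index=gene_ids,
            columns=[f"S{j + 1:02d}" for j in range(n_s)],
        )
        df.index.name = "gene_id"
        datasets.append(ExpressionMatrix(df, RNASEQ))
    truth = expected_link_set(cfg)
    truth.target_module = target_module
    return datasets, truth


def annotation_frame(cfg: SyntheticConfig, brain_grfs=()) -> pd.DataFrame:
    """Node annotation for the synthetic catalog: all GRFs flagged is_grf."""
    brain = set(brain_grfs)
    rows = [
        {
            "gene_id": g,
            "is_grf": True,
            "is_brain_grf": g in brain,
            "label": "grf",
        }
        for g in cfg.grf_ids
    ] + [
        {"gene_id": t, "is_grf": False, "is_brain_grf": False, "label": "target"}
        for t in cfg.target_ids
    ]
    return pd.DataFrame(rows).set_index("gene_id")


def write_simulation(cfg: SyntheticConfig, out_dir: str | Path) -> dict:
    """Write D expression TSVs, the annotation TSV, and the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    datasets, truth = generate_multiset(cfg)
    paths = {"datasets": [], "annotation": None, "ground_truth": None}
    for d, mat in enumerate(datasets):
        p = out / f"dataset_{d:02d}.tsv"
        mat.data.to_csv(p, sep="\t", float_format="%.17g")
        paths["datasets"].append(str(p))
    ann_path = out / "annotation.tsv"
    annotation_frame(cfg).to_csv(ann_path, sep="\t")
    paths["annotation"] = str(ann_path)
    gt_path = out / "ground_truth.tsv"
    truth.links.to_csv(gt_path, sep="\t", index=False)
    paths["ground_truth"] = str(gt_path)
    return paths
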