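"""End-to-end orchestration: filter -> correlate -> wTO (per dataset) ->
optional null calibration -> consensus -> hub analysis.

Driven by a YAML/dict configuration; every run writes per-dataset edge
lists, the consensus edge list, a node-degree table, and a JSON manifest
recording versions, seeds, parameters, and per-stage counts.  Reruns with
the same configuration and seed reproduce outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .consensus import align_networks, build_consensus, mean_calibrated_cutoff
from .expression import RNASEQ, ExpressionMatrix, filter_rpkm, read_annotation, read_expression
from .netio import write_edge_list
from .synthetic import ModuleSpec, SyntheticConfig, generate_multiset, annotation_frame
from .wto import DEFAULT_CUTOFFS, calibrate_null, wto_from_expression
from .analysis import degrees, hubs

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``datasets`` (paths to expression TSVs, with
    ``annotation`` path) or ``synthetic`` (a SyntheticConfig mapping) must
    be given.  Every stochastic stage derives its stream from ``seed``.
    """

    output_dir: str
    seed: int
    datasets: list[str] = field(default_factory=list)
    annotation: str | None = None
    synthetic: dict | None = None
    rpkm_min: float = 0.5
    rpkm_fraction: float = 0.9
    alpha: float = 0.05
    overlap_set: str = "all_genes"
    calibrate: bool = False
    n_perm: int = 100
    cutoffs: tuple = DEFAULT_CUTOFFS
    consensus_threshold: float = 0.3
    auto_threshold: bool = False
    consensus_alpha: float = 0.05
    min_present: int | None = None
    hub_min_degree: int = 25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration fields: {sorted(unknown)}")
        for req in ("output_dir", "seed"):
            if req not in raw:
                raise ValueError(f"missing required configuration field: {req}")
        cfg = cls(**raw)
        if bool(cfg.datasets) == bool(cfg.synthetic):
            raise ValueError("provide exactly one of 'datasets' or 'synthetic'")
        if cfg.datasets and not cfg.annotation:
            raise ValueError("'annotation' is required with file-based datasets")
        if cfg.auto_threshold and not cfg.calibrate:
            raise ValueError("'auto_threshold' requires 'calibrate: true'")
        return cfg


def _synthetic_config(raw: dict, seed: int) -> SyntheticConfig:
    raw = dict(raw)
    raw.setdefault("seed", seed)
    if "modules" in raw and raw["modules"] is not None:
        raw["modules"] = [
            m if isinstance(m, ModuleSpec) else ModuleSpec(**m) for m in raw["modules"]
        ]
    return SyntheticConfig(**raw)


def run_pipeline(config: RunConfig | dict | str | Path) -> dict:
    """Execute the full pipeline and return the run manifest.

    Any stage failure aborts with the stage name and offending input in
    the exception message.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "wtonet_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in {"synthetic"}
        },
        "stages": {},
        "outputs": [],
    }

    # --- load / generate ---------------------------------------------------
    if config.synthetic is not None:
        syn = _synthetic_config(config.synthetic, config.seed)
        mats, truth = generate_multiset(syn)
        tags = [f"ds{d:02d}" for d in range(len(mats))]
        annotation = annotation_frame(syn)
        manifest["stages"]["generate"] = {
            "n_datasets": len(mats),
            "expected_links": int(len(truth.links)),
        }
    else:
        mats, tags = [], []
        for p in config.datasets:
            try:
                mats.append(read_expression(p))
            except Exception as exc:
                raise RuntimeError(f"stage 'load' failed for input {p}: {exc}") from exc
            tags.append(Path(p).stem)
        annotation = read_annotation(config.annotation)
        manifest["stages"]["load"] = {"n_datasets": len(mats)}
    grf_ids = sorted(annotation.index[annotation["is_grf"]])

    # --- filter ------------------------------------------------------------
    filtered: list[ExpressionMatrix] = []
    for tag, mat in zip(tags, mats):
        if mat.platform_tag == RNASEQ:
            try:
                mat = filter_rpkm(mat, config.rpkm_min, config.rpkm_fraction)
            except Exception as exc:
                raise RuntimeError(f"stage 'filter' failed for dataset {tag}: {exc}") from exc
        filtered.append(mat)
    manifest["stages"]["filter"] = {
        tag: {"n_genes": m.n_genes, "n_samples": m.n_samples}
        for tag, m in zip(tags, filtered)
    }

    # --- per-dataset wTO ---------------------------------------------------
    nets = []
    for tag, mat in zip(tags, filtered):
        try:
            net = wto_from_expression(
                mat, grf_ids, alpha=config.alpha,
                overlap_set=config.overlap_set, dataset_tag=tag,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'wto' failed for dataset {tag}: {exc}") from exc
        nets.append(net)
        p = out / f"wto_{tag}.tsv"
        write_edge_list(net, p, cutoff=0.0)
        manifest["outputs"].append(str(p))
    manifest["stages"]["wto"] = {
        tag: {"n_grfs": len(n.grf_ids), "links_gt_0.3": n.link_count(0.3)}
        for tag, n in zip(tags, nets)
    }

    # --- optional calibration ---------------------------------------------
    threshold = config.consensus_threshold
    if config.calibrate:
        calibs = []
        for d, (tag, mat) in enumerate(zip(tags, filtered)):
            calib = calibrate_null(
                mat, grf_ids, n_perm=config.n_perm, cutoffs=config.cutoffs,
                alpha=config.alpha, overlap_set=config.overlap_set,
                seed=(config.seed * 1000 + d) % (2**31),
            )
            calibs.append(calib)
            p = out / f"calibration_{tag}.tsv"
            calib.to_frame().to_csv(p, sep="\t", index=False, float_format="%.17g")
            manifest["outputs"].append(str(p))
        manifest["stages"]["calibrate"] = {
            tag: {"recommended_cutoff": c.recommended_cutoff}
            for tag, c in zip(tags, calibs)
        }
        if config.auto_threshold:
            threshold = mean_calibrated_cutoff(calibs)
            manifest["stages"]["calibrate"]["auto_threshold"] = threshold

    # --- consensus ---------------------------------------------------------
    try:
        stack = align_networks(nets, dataset_ids=tags)
        cons = build_consensus(
            stack, threshold=threshold, alpha=config.consensus_alpha,
            min_present=config.min_present,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'consensus' failed: {exc}") from exc
    p = out / "consensus.tsv"
    write_edge_list(cons, p)
    manifest["outputs"].append(str(p))
    manifest["stages"]["consensus"] = {
        "threshold": threshold,
        "n_links": cons.n_links,
        "n_nodes": len(cons.node_ids),
    }

    # --- analysis ----------------------------------------------------------
    deg = degrees(cons)
    p = out / "degrees.tsv"
    deg.to_csv(p, sep="\t")
    manifest["outputs"].append(str(p))
    hub_list = hubs(deg, config.hub_min_degree)
    manifest["stages"]["analysis"] = {
        "hub_min_degree": config.hub_min_degree,
        "n_hubs": len(hub_list),
        "hubs": hub_list,
    }

    manifest_path = out / "manifest.json"
    manifest["outputs"].append(str(manifest_path))
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
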