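"""Network export and import: TSV edge lists, GraphML, and SIF.

All exports are deterministic given the network: edges are sorted
lexicographically by canonical pair (grf_a < grf_b) and floats are written
at full round-trip precision (%.17g).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .consensus import ConsensusNetwork
from .wto import WTONetwork

FLOAT_FMT = "%.17g"
FORMATS = ("tsv", "graphml", "sif")


def _edge_frame(net: ConsensusNetwork | WTONetwork, cutoff: float | None) -> pd.DataFrame:
    if isinstance(net, ConsensusNetwork):
        df = net.links.copy()
        df = df.rename(columns={"median_wto": "wto"})
        return df
    if isinstance(net, WTONetwork):
        if cutoff is None:
            cutoff = 0.0
        return net.edges(cutoff)
    raise TypeError(f"unsupported network type {type(net).__name__}")


def write_edge_list(
    net: ConsensusNetwork | WTONetwork,
    path: str | Path,
    cutoff: float | None = None,
) -> Path:
    """Write a TSV edge list (grf_a, grf_b, wto[, p_value, ...])."""
    df = _edge_frame(net, cutoff)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an edge list written by :func:`write_edge_list`."""
    df = pd.read_csv(path, sep="\t")
    if not {"grf_a", "grf_b", "wto"} <= set(df.columns):
        raise ValueError(f"{path} is not a wtonet edge list")
    return df


def to_networkx(
    net: ConsensusNetwork | WTONetwork,
    cutoff: float | None = None,
    annotations: pd.DataFrame | None = None,
) -> nx.Graph:
    """Build an undirected graph with node and edge attributes.

    Node attributes: degree, plus is_grf/is_brain_grf when an annotation
    table is supplied.  Edge attributes: wto, sign ("pos"/"neg"), and
    p_value for consensus links.
    """
    df = _edge_frame(net, cutoff)
    g = nx.Graph()
    for row in df.itertuples(index=False):
        attrs = {"wto": float(row.wto), "sign": "pos" if row.wto > 0 else "neg"}
        if hasattr(row, "p_value"):
            attrs["p_value"] = float(row.p_value)
        g.add_edge(row.grf_a, row.grf_b, **attrs)
    deg = dict(g.degree())
    for node in g.nodes:
        g.nodes[node]["degree"] = deg[node]
        if annotations is not None and node in annotations.index:
            g.nodes[node]["is_grf"] = bool(annotations.loc[node, "is_grf"])
            g.nodes[node]["is_brain_grf"] = bool(annotations.loc[node, "is_brain_grf"])
    return g


def export_network(
    net: ConsensusNetwork | WTONetwork,
    path: str | Path,
    format: str = "tsv",
    annotations: pd.DataFrame | None = None,
    cutoff: float | None = None,
) -> Path:
    """Export a network for downstream tools (e.g. Cytoscape import).

    ``tsv`` — edge list; ``graphml`` — GraphML 1.0 with node/edge
    attributes; ``sif`` — simple interaction format with interaction type
    "pos"/"neg" by wTO sign plus a companion ``<path>.nodes.tsv`` attribute
    table.
    """
    path = Path(path)
    if format == "tsv":
        return write_edge_list(net, path, cutoff)
    if format == "graphml":
        g = to_networkx(net, cutoff, annotations)
        nx.write_graphml(g, path)
        return path
    if format == "sif":
        df = _edge_frame(net, cutoff)
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                rel = "pos" if row.wto > 0 else "neg"
                fh.write(f"{row.grf_a}\t{rel}\t{row.grf_b}\n")
        nodes = sorted(set(df["grf_a"]) | set(df["grf_b"]))
        node_rows = []
        deg = pd.concat([df["grf_a"], df["grf_b"]]).value_counts()
        for n in nodes:
            rec = {"gene_id": n, "degree": int(deg.get(n, 0))}
            if annotations is not None and n in annotations.index:
                rec["is_grf"] = bool(annotations.loc[n, "is_grf"])
                rec["is_brain_grf"] = bool(annotations.loc[n, "is_brain_grf"])
            node_rows.append(rec)
        pd.DataFrame(node_rows).to_csv(
            path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False
        )
        return path
    raise ValueError(f"unknown format {format!r}; supported: {FORMATS}")


def read_gene_set(path: str | Path) -> list[str]:
    """Read a plain-text gene list (one identifier per line, # comments)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
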