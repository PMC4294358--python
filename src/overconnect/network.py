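"""Directed, signed, class-annotated interaction network model and I/O.

The network stands in for a curated regulatory database: nodes are genes,
edges are directed regulatory interactions with an effect sign (activation /
inhibition / unspecified), and every node carries a molecular class
(transcription factor, kinase, protease, or other). The node universe defines
N for the over-connectivity statistic and a hub's distinct outgoing targets
define its R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_TOKENS = ("transcription_factor", "kinase", "protease", "other")
EFFECT_TOKENS = ("activation", "inhibition", "unspecified")


class NetworkLoadError(ValueError):
    """Raised when an edge list or class annotation fails validation."""


@dataclass
class InteractionNetwork:
    """Directed signed interaction network with node class annotations.

    Backed by a :class:`networkx.DiGraph`; nodes carry a ``node_class``
    attribute (defaulting to ``other``) and edges carry an ``effect``
    attribute. No self-loops; at most one edge per ordered pair.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_universe(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_class(self, node: str) -> str:
        if node not in self.graph:
            raise KeyError(f"node {node!r} not in network")
        return self.graph.nodes[node].get("node_class", "other")

    def effect(self, source: str, target: str) -> str:
        return self.graph.edges[source, target]["effect"]

    def out_targets(self, hub: str) -> set[str]:
        """Distinct outgoing targets of a hub; their count is the hub's R."""
        if hub not in self.graph:
            raise KeyError(f"hub {hub!r} not in network")
        return set(self.graph.successors(hub))

    def neighbors_any_direction(self, hub: str) -> set[str]:
        """All neighbors regardless of edge direction (undirected R mode)."""
        if hub not in self.graph:
            raise KeyError(f"hub {hub!r} not in network")
        return set(self.graph.successors(hub)) | set(self.graph.predecessors(hub))

    def nodes_of_class(self, cls: str) -> set[str]:
        if cls not in CLASS_TOKENS:
            raise ValueError(f"unknown class token {cls!r}; expected one of {CLASS_TOKENS}")
        return {n for n in self.graph.nodes if self.node_class(n) == cls}


def build_network(edges: list[tuple[str, str, str]],
                  classes: dict[str, str] | None = None,
                  extra_nodes: set[str] | None = None) -> InteractionNetwork:
    """Assemble a validated network from in-memory edges and class labels.

    Self-loops are dropped (logged); duplicate ordered pairs collapse keeping
    the first non-``unspecified`` effect seen.
    """
    classes = classes or {}
    g = nx.DiGraph()
    n_self = 0
    for src, tgt, eff in edges:
        if eff not in EFFECT_TOKENS:
            raise NetworkLoadError(
                f"unknown effect token {eff!r} on edge {src}->{tgt}; "
                f"expected one of {EFFECT_TOKENS}"
            )
        if src == tgt:
            n_self += 1
            continue
        if g.has_edge(src, tgt):
            if g.edges[src, tgt]["effect"] == "unspecified" and eff != "unspecified":
                g.edges[src, tgt]["effect"] = eff
            continue
        g.add_edge(src, tgt, effect=eff)
    if n_self:
        logger.warning("dropped %d self-loop edge(s)", n_self)
    for node in extra_nodes or ():
        g.add_node(node)
    for gene, cls in classes.items():
        if cls not in CLASS_TOKENS:
            raise NetworkLoadError(
                f"unknown class token {cls!r} for gene {gene!r}; "
                f"expected one of {CLASS_TOKENS}"
            )
        g.add_node(gene)
    nx.set_node_attributes(
        g, {n: classes.get(n, "other") for n in g.nodes}, "node_class"
    )
    return InteractionNetwork(g)


def load_network(edges_path: str | Path, classes_path: str | Path | None = None
                 ) -> InteractionNetwork:
    """Load an edge-list TSV (source, target[, effect]) and class TSV (gene, class)."""
    edf = pd.read_csv(edges_path, sep="\t", dtype=str)
    for col in ("source", "target"):
        if col not in edf.columns:
            raise NetworkLoadError(f"{edges_path}: missing required column '{col}'")
    if "effect" not in edf.columns:
        edf["effect"] = "unspecified"
    edf["effect"] = edf["effect"].fillna("unspecified")
    edges = list(edf[["source", "target", "effect"]].itertuples(index=False, name=None))
    classes: dict[str, str] = {}
    if classes_path is not None:
        cdf = pd.read_csv(classes_path, sep="\t", dtype=str)
        for col in ("gene", "class"):
            if col not in cdf.columns:
                raise NetworkLoadError(f"{classes_path}: missing required column '{col}'")
        classes = dict(zip(cdf["gene"], cdf["class"]))
    net = build_network(edges, classes)
    if net.n_universe <= 1:
        raise NetworkLoadError(
            f"network has {net.n_universe} node(s); the over-connectivity "
            "statistic is undefined for a universe smaller than 2"
        )
    return net


def save_network(net: InteractionNetwork, edges_path: str | Path,
                 classes_path: str | Path) -> None:
    """Write the network back as sorted edge-list and class TSVs (round-trippable)."""
    rows = sorted(
        (s, t, d["effect"]) for s, t, d in net.graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["source", "target", "effect"]).to_csv(
        edges_path, sep="\t", index=False
    )
    crows = sorted((n, net.node_class(n)) for n in net.graph.nodes)
    pd.DataFrame(crows, columns=["gene", "class"]).to_csv(
        classes_path, sep="\t", index=False
    )


def export_graphml(net: InteractionNetwork, out_path: str | Path) -> None:
    """Deterministic GraphML export (nodes and edges inserted sorted)."""
    g = nx.DiGraph()
    for n in sorted(net.graph.nodes):
        g.add_node(n, node_class=net.node_class(n))
    for s, t in sorted(net.graph.edges):
        g.add_edge(s, t, effect=net.effect(s, t))
    nx.write_graphml(g, out_path)


_DOT_COLOR = {"activation": "green", "inhibition": "red", "unspecified": "gray"}


def export_dot(net: InteractionNetwork, out_path: str | Path) -> None:
    """Deterministic DOT export; edge colors green/red/gray by effect sign."""
    lines = ["digraph interactome {"]
    for n in sorted(net.graph.nodes):
        lines.append(f'  "{n}" [node_class="{net.node_class(n)}"];')
    for s, t in sorted(net.graph.edges):
        eff = net.effect(s, t)
        lines.append(f'  "{s}" -> "{t}" [color={_DOT_COLOR[eff]}, effect="{eff}"];')
    lines.append("}")
    Path(out_path).write_text("\n".join(lines) + "\n")


def load_inhibitors(path: str | Path) -> pd.DataFrame:
    """Inhibitor table: target_gene, compound, annotation (duplicates allowed)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("target_gene", "compound"):
        if col not in df.columns:
            raise NetworkLoadError(f"{path}: missing required column '{col}'")
    if "annotation" not in df.columns:
        df["annotation"] = ""
    df["annotation"] = df["annotation"].fillna("")
    if (df["target_gene"].str.len() == 0).any():
        raise NetworkLoadError(f"{path}: empty target_gene value")
    return df[["target_gene", "compound", "annotation"]]
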