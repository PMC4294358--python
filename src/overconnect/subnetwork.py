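"""Seed-rooted signed subnetwork reconstruction with per-group regulation state.

Starting from a seed regulator, the parent network is expanded breadth-first
over both outgoing and incoming edges up to a hop limit; by default only
nodes differentially expressed in at least one experimental group are kept
(plus the seed itself). Each kept node is annotated, per group, as up / down
(significant with that direction), unchanged (measured, not significant) or
unmeasured, mirroring the red/blue per-group bars of a curated pathway
figure; edges keep their activation/inhibition/unspecified sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .network import InteractionNetwork

STATES = ("up", "down", "unchanged", "unmeasured")


@dataclass
class SubnetworkModel:
    """A seed-rooted signed subgraph with per-(node, group) regulation states."""

    seed: str
    graph: nx.DiGraph                      # induced subgraph, edge attr 'effect'
    group_labels: list[str]
    state_of: dict[tuple[str, str], str]   # (node, group label) -> state

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def _node_state(gene: str, de: pd.DataFrame | dict) -> str:
    if isinstance(de, pd.DataFrame):
        de = dict(zip(de["gene_id"], de["direction"]))
    direction = de.get(gene)
    if direction is None:
        return "unmeasured"
    return direction if direction in ("up", "down") else "unchanged"


def reconstruct(net: InteractionNetwork, seed: str,
                de_by_group: list[pd.DataFrame],
                depth: int = 2, de_only: bool = True,
                group_labels: list[str] | None = None) -> SubnetworkModel:
    """Depth-bounded bidirectional BFS from the seed with a DE filter.

    Nodes within ``depth`` hops of the seed along outgoing or incoming edges
    are candidates; with ``de_only`` only those significant in at least one
    group survive (the seed always does). States are read from the per-group
    DE tables.
    """
    if seed not in net.nodes:
        raise KeyError(f"seed {seed!r} not in network")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if group_labels is None:
        group_labels = [f"group_{i + 1}" for i in range(len(de_by_group))]
    if len(group_labels) != len(de_by_group):
        raise ValueError("one label per DE table required")

    g = net.graph
    fwd = nx.single_source_shortest_path_length(g, seed, cutoff=depth)
    bwd = nx.single_source_shortest_path_length(g.reverse(copy=False), seed,
                                                cutoff=depth)
    candidates = set(fwd) | set(bwd)

    direction_maps = [dict(zip(de["gene_id"], de["direction"]))
                     for de in de_by_group]
    kept = set()
    for node in candidates:
        if node == seed:
            kept.add(node)
            continue
        states = [_node_state(node, dm) for dm in direction_maps]
        if not de_only or any(s in ("up", "down") for s in states):
            kept.add(node)

    sub = nx.DiGraph()
    for node in sorted(kept):
        sub.add_node(node, node_class=net.node_class(node))
    for s, t in sorted(g.edges):
        if s in kept and t in kept:
            sub.add_edge(s, t, effect=net.effect(s, t))

    state_of = {
        (node, label): _node_state(node, dm)
        for node in kept
        for label, dm in zip(group_labels, direction_maps)
    }
    return SubnetworkModel(seed, sub, list(group_labels), state_of)


_DOT_COLOR = {"activation": "green", "inhibition": "red", "unspecified": "gray"}
_STATE_FILL = {"up": "#e06060", "down": "#6080e0",
               "unchanged": "#ffffff", "unmeasured": "#d9d9d9"}


def export_subnetwork(model: SubnetworkModel, out_path: str | Path,
                      format: str = "graphml") -> None:
    """Serialize the model deterministically as GraphML or DOT.

    Nodes carry one ``state_<group>`` attribute per group; edges carry their
    ``effect`` (rendered green/red/gray in DOT for activation / inhibition /
    unspecified).
    """
    if model.graph.number_of_nodes() == 0:
        raise ValueError("empty subnetwork model")
    if format == "graphml":
        g = nx.DiGraph()
        for node in sorted(model.graph.nodes):
            attrs = {f"state_{label}": model.state_of[(node, label)]
                     for label in model.group_labels}
            attrs["is_seed"] = node == model.seed
            g.add_node(node, **attrs)
        for s, t in sorted(model.graph.edges):
            g.add_edge(s, t, effect=model.graph.edges[s, t]["effect"])
        nx.write_graphml(g, out_path)
    elif format == "dot":
        lines = ["digraph subnetwork {"]
        for node in sorted(model.graph.nodes):
            states = ", ".join(
                f'state_{label}="{model.state_of[(node, label)]}"'
                for label in model.group_labels
            )
            shape = "box" if node == model.seed else "ellipse"
            lines.append(f'  "{node}" [shape={shape}, {states}];')
        for s, t in sorted(model.graph.edges):
            eff = model.graph.edges[s, t]["effect"]
            lines.append(
                f'  "{s}" -> "{t}" [color={_DOT_COLOR[eff]}, effect="{eff}"];'
            )
        lines.append("}")
        Path(out_path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'graphml' or 'dot'")
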