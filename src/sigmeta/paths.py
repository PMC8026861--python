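"""Shortest-path exploration over signed networks with polarity composition.

All minimum-hop directed paths between two entities are enumerated (paths
are simple; hop count is the metric — the literature network carries no
edge weights).  Each path's net regulatory sign is the product of its edge
polarities.  Intermediate nodes are classified by their direct edge into
the target disease: promoter (+), inhibitor (−) or indirect (no direct
edge); the overall verdict is "mixed" when both promoter- and
inhibitor-class intermediates occur on the paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .relations import Relation, SignedNetwork

DEFAULT_MAX_PATHS = 100


@dataclass(frozen=True)
class SignedPath:
    nodes: tuple[str, ...]
    edge_polarities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) - 1 != len(self.edge_polarities):
            raise ValueError("polarity list must have one entry per edge")

    @property
    def length(self) -> int:
        return len(self.edge_polarities)

    @property
    def net_sign(self) -> int:
        return math.prod(self.edge_polarities)


def shortest_paths(
    network: SignedNetwork,
    source: str,
    target: str,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> list[SignedPath]:
    """All directed minimum-hop paths from source to target, signed.

    Returns up to ``max_paths`` paths in lexicographic node-sequence
    order.  No path at all yields an empty list; identical endpoints are
    rejected.
    """
    source, target = source.upper(), target.upper()
    if source == target:
        raise ValueError("source and target must differ")
    for node in (source, target):
        if node not in network:
            raise KeyError(f"node {node!r} not in network")
    try:
        raw = sorted(nx.all_shortest_paths(network.graph, source, target))
    except nx.NetworkXNoPath:
        return []
    paths = [
        SignedPath(
            nodes=tuple(p),
            edge_polarities=tuple(
                network.graph.edges[u, v]["polarity"] for u, v in zip(p, p[1:])
            ),
        )
        for p in raw[:max_paths]
    ]
    return paths


def classify_intermediates(
    paths: Sequence[SignedPath],
    relations: Sequence[Relation],
    disease: str,
) -> tuple[pd.DataFrame, str]:
    """Label each intermediate node by its direct edge into ``disease``.

    Roles: ``promoter`` for a positive node -> disease edge, ``inhibitor``
    for a negative one, ``indirect`` when no direct edge exists.  The
    verdict is ``"mixed"`` when both promoters and inhibitors occur,
    otherwise ``"promoting"`` / ``"inhibiting"`` / ``"indirect"``.
    """
    disease = disease.upper()
    net = SignedNetwork.from_relations(relations)
    intermediates: list[str] = []
    seen: set[str] = set()
    for path in paths:
        for node in path.nodes[1:-1]:
            if node not in seen:
                seen.add(node)
                intermediates.append(node)
    rows = []
    for node in intermediates:
        sign = net.edge_sign(node, disease)
        role = "indirect" if sign is None else ("promoter" if sign > 0 else "inhibitor")
        rows.append({"node": node, "role": role})
    table = pd.DataFrame(rows, columns=["node", "role"])
    roles = set(table["role"]) if not table.empty else set()
    if {"promoter", "inhibitor"} <= roles:
        verdict = "mixed"
    elif "promoter" in roles:
        verdict = "promoting"
    elif "inhibitor" in roles:
        verdict = "inhibiting"
    else:
        verdict = "indirect"
    return table, verdict


def paths_table(paths: Sequence[SignedPath]) -> pd.DataFrame:
    """Paths as a TSV-ready table: ordered nodes, polarities, net sign."""
    return pd.DataFrame(
        [
            {
                "nodes": "->".join(p.nodes),
                "polarities": ",".join(f"{s:+d}" for s in p.edge_polarities),
                "length": p.length,
                "net_sign": p.net_sign,
            }
            for p in paths
        ],
        columns=["nodes", "polarities", "length", "net_sign"],
    )


def to_dot(network: SignedNetwork, path: str | Path) -> None:
    """Write a DOT file; negative edges are drawn with tee arrowheads."""
    lines = ["digraph signed {"]
    for node in sorted(network.graph.nodes):
        lines.append(f'  "{node}";')
    for u, v, d in sorted(network.graph.edges(data=True)):
        arrow = "normal" if d["polarity"] > 0 else "tee"
        lines.append(f'  "{u}" -> "{v}" [arrowhead={arrow}, polarity={d["polarity"]:+d}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
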