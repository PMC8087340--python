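"""Typed relation graph, community detection and network summaries.

The cohort's typed relations become a simple undirected graph: one edge
per unordered pair, carrying the *set* of relation types observed for
that pair.  Nodes carry the participant's BMI, BMI category and
composite score so that exports can be visualised directly.  Communities
are detected with the Louvain modularity heuristic (seeded, so results
are reproducible); isolated participants each form a singleton
community.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import pandas as pd
from pydantic import BaseModel, Field

from .domain import BMICategory, Cohort, DomainError, bmi_category
from .scoring import ScoreCard

__all__ = [
    "CommunityPartition",
    "NetworkSummary",
    "build_graph",
    "detect_communities",
    "network_summary",
    "color_for_bmi",
    "ego_table",
    "export_graph",
    "import_graph",
    "round_half_up",
]

_COLORS: dict[BMICategory, str] = {
    BMICategory.underweight: "blue",
    BMICategory.normal: "green",
    BMICategory.overweight: "yellow",
    BMICategory.obesity1: "red",
    BMICategory.obesity2: "red",
    BMICategory.obesity3: "red",
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, the convention used for printed percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def color_for_bmi(bmi: float) -> str:
    """Node colour: blue <18.5, green [18.5,25), yellow [25,30), red >=30."""
    return _COLORS[bmi_category(bmi)]


class CommunityPartition(BaseModel):
    """Node -> community id (contiguous from 0)."""

    membership: dict[str, int]

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.membership.values():
            out[c] = out.get(c, 0) + 1
        return out

    def members(self, community: int) -> list[str]:
        return sorted(u for u, c in self.membership.items() if c == community)


class CommunityStats(BaseModel):
    community: int
    size: int
    bmi_counts: dict[str, int]
    bmi_percent: dict[str, float]


class NetworkSummary(BaseModel):
    n_nodes: int
    n_edges: int
    n_isolated: int
    n_communities: int
    n_communities_multi: int
    largest_community: int
    communities: list[CommunityStats] = Field(default_factory=list)


def build_graph(
    cohort: Cohort, scorecards: Mapping[str, ScoreCard]
) -> nx.Graph:
    """Simple undirected graph over scored participants.

    Nodes: every scored user, isolated ones included, with ``bmi``,
    ``bmi_cat``, ``wakastatus`` and ``color`` attributes.  Duplicate
    typed relations for a pair merge into one edge whose ``rel_types``
    attribute is the set of types.  A relation endpoint without a
    scorecard is an error naming the relation.
    """
    g = nx.Graph()
    for uid in sorted(scorecards):
        sc = scorecards[uid]
        g.add_node(
            uid,
            bmi=sc.bmi,
            bmi_cat=sc.bmi_cat.value,
            wakastatus=sc.wakastatus,
            color=color_for_bmi(sc.bmi),
        )
    for r in cohort.relations:
        for endpoint in (r.user_a, r.user_b):
            if endpoint not in scorecards:
                raise DomainError(
                    f"relation {r.key()} references unscored user {endpoint!r}"
                )
        if g.has_edge(r.user_a, r.user_b):
            g.edges[r.user_a, r.user_b]["rel_types"].add(r.relation_type.value)
        else:
            g.add_edge(r.user_a, r.user_b, rel_types={r.relation_type.value})
    return g


def detect_communities(
    graph: nx.Graph, seed: int = 0, resolution: float = 1.0
) -> CommunityPartition:
    """Louvain modularity communities, deterministic for a fixed seed.

    Community ids are relabelled contiguously from 0 in order of each
    community's smallest node id, so the labelling does not depend on
    the heuristic's internal ordering.
    """
    if graph.number_of_nodes() == 0:
        return CommunityPartition(membership={})
    comms = nx.community.louvain_communities(graph, resolution=resolution, seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    membership = {u: k for k, c in enumerate(comms) for u in c}
    return CommunityPartition(membership=membership)


def network_summary(graph: nx.Graph, partition: CommunityPartition) -> NetworkSummary:
    """Counts and per-community BMI-category composition.

    Percentages are rounded half-up to one decimal, the printing
    convention for cohort shares.
    """
    sizes = partition.sizes()
    stats: list[CommunityStats] = []
    for cid in sorted(sizes):
        members = partition.members(cid)
        counts: dict[str, int] = {}
        for u in members:
            cat = graph.nodes[u]["bmi_cat"]
            counts[cat] = counts.get(cat, 0) + 1
        pct = {
            cat: round_half_up(100.0 * cnt / len(members)) for cat, cnt in counts.items()
        }
        stats.append(
            CommunityStats(
                community=cid, size=len(members), bmi_counts=counts, bmi_percent=pct
            )
        )
    return NetworkSummary(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        n_isolated=sum(1 for _, d in graph.degree() if d == 0),
        n_communities=len(sizes),
        n_communities_multi=sum(1 for s in sizes.values() if s > 1),
        largest_community=max(sizes.values(), default=0),
        communities=stats,
    )


def ego_table(graph: nx.Graph, user_id: str) -> pd.DataFrame:
    """Neighbours of one user with their relation types, BMI and scores.

    Sorted by composite score descending, ties broken by neighbour id.
    """
    if user_id not in graph:
        raise KeyError(f"unknown user {user_id!r}")
    rows = []
    for nb in graph.neighbors(user_id):
        d = graph.nodes[nb]
        rows.append(
            {
                "neighbor_id": nb,
                "rel_types": ",".join(sorted(graph.edges[user_id, nb]["rel_types"])),
                "bmi": d["bmi"],
                "bmi_category": d["bmi_cat"],
                "wakastatus": d["wakastatus"],
            }
        )
    df = pd.DataFrame(
        rows, columns=["neighbor_id", "rel_types", "bmi", "bmi_category", "wakastatus"]
    )
    if len(df):
        df = df.sort_values(
            ["wakastatus", "neighbor_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def _annotated_copy(graph: nx.Graph, partition: Optional[CommunityPartition]) -> nx.Graph:
    g = graph.copy()
    if partition is not None:
        for u, c in partition.membership.items():
            if u in g:
                g.nodes[u]["community"] = int(c)
    for _, _, d in g.edges(data=True):
        d["rel_types"] = ",".join(sorted(d["rel_types"]))
    return g


def export_graph(
    graph: nx.Graph,
    partition: Optional[CommunityPartition],
    path: str | Path,
    format: str = "graphml",
) -> None:
    """Write the annotated graph as GraphML or node-link JSON.

    Edge type sets are serialised as comma-joined strings;
    :func:`import_graph` reverses this, so export/import round-trips.
    """
    g = _annotated_copy(graph, partition)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "json":
        data = nx.node_link_data(g, edges="links")
        path.write_text(json.dumps(data, indent=1, sort_keys=True), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'graphml' or 'json')")


def import_graph(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a graph written by :func:`export_graph`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
    elif format == "json":
        g = nx.node_link_graph(json.loads(path.read_text(encoding="utf-8")), edges="links")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'graphml' or 'json')")
    for _, _, d in g.edges(data=True):
        if isinstance(d.get("rel_types"), str):
            d["rel_types"] = set(d["rel_types"].split(","))
    return g
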