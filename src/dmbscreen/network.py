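"""Greedy confidence-weighted expansion of a gene-interaction network from
seed genes, and hub-candidate ranking within the expanded subgraph.

Starting from the seed genes, the expansion repeatedly admits the outside
node with the strongest single edge into the current member set until a
target size is reached — a simple deterministic analogue of the
neighborhood-expansion features of interaction databases, operating purely
on a supplied weighted edge list. Within the induced subgraph, non-seed
nodes are ranked by weighted degree to propose hub candidates, and the
component structure shows which seeds hang together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class WeightedNetwork:
    """Undirected gene graph with per-edge confidence in (0, 1]."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop at {u}")
            c = d.get("confidence")
            if c is None or not 0 < c <= 1:
                raise ValueError(f"edge {u}-{v}: confidence {c!r} not in (0,1]")

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str, float]],
        nodes: list[str] | None = None,
    ) -> "WeightedNetwork":
        g = nx.Graph()
        if nodes:
            g.add_nodes_from(nodes)
        for u, v, c in edges:
            if g.has_edge(u, v):
                raise ValueError(f"duplicate edge {u}-{v}")
            g.add_edge(u, v, confidence=float(c))
        return cls(g)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WeightedNetwork":
        cols = list(df.columns[:3])
        return cls.from_edges(
            list(df[cols].itertuples(index=False, name=None))
        )

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


@dataclass
class ExpansionResult:
    """Members of the expanded subnetwork, in addition order, with the
    induced subgraph."""

    members: list[str]
    seeds: list[str]
    subgraph: nx.Graph = field(repr=False)

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.subgraph)]

    def weighted_degree(self, node: str) -> float:
        return float(
            sum(d["confidence"] for _, _, d in self.subgraph.edges(node, data=True))
        )


def expand_network(
    net: WeightedNetwork,
    seeds: list[str],
    target_n: int = 50,
    min_confidence: float = 0.9,
) -> ExpansionResult:
    """Grow the member set greedily from *seeds* to *target_n* nodes.

    Edges below *min_confidence* are discarded first ("highest confidence"
    associations only). Each round admits the non-member with the highest
    best-edge confidence to the member set; ties break by summed confidence
    to members, then lexicographic node id, making the result deterministic
    and independent of edge-list order. Expansion stops early when no
    remaining node touches the members.
    """
    if not seeds:
        raise ValueError("seeds must be non-empty")
    missing = [s for s in seeds if s not in net.graph]
    if missing:
        raise KeyError(f"seed gene(s) not in network: {missing}")
    if target_n < 1:
        raise ValueError("target_n must be >= 1")

    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        if d["confidence"] >= min_confidence:
            g.add_edge(u, v, confidence=d["confidence"])

    members: list[str] = list(dict.fromkeys(seeds))
    member_set = set(members)
    while len(members) < target_n:
        best = None
        for node in g.nodes:
            if node in member_set:
                continue
            confs = [
                g[node][m]["confidence"] for m in g.neighbors(node) if m in member_set
            ]
            if not confs:
                continue
            key = (max(confs), sum(confs), node)
            if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                (key[0], key[1]) == (best[0], best[1]) and node < best[2]
            ):
                best = key
        if best is None:
            logger.info("expansion exhausted at %d members", len(members))
            break
        members.append(best[2])
        member_set.add(best[2])
    sub = net.graph.subgraph(members).copy()
    # drop induced edges below the confidence floor as well
    for u, v, d in list(sub.edges(data=True)):
        if d["confidence"] < min_confidence:
            sub.remove_edge(u, v)
    return ExpansionResult(members=members, seeds=list(seeds), subgraph=sub)


def hub_candidates(result: ExpansionResult) -> pd.DataFrame:
    """Rank non-seed members by weighted degree in the induced subgraph.

    Ties break by unweighted degree, then lexicographic symbol. The
    ``seeds_in_component`` column counts seeds sharing a connected
    component with each candidate.
    """
    seeds = set(result.seeds)
    comps = result.components
    rows = []
    for node in result.members:
        if node in seeds:
            continue
        comp = next(c for c in comps if node in c)
        rows.append(
            {
                "gene_symbol": node,
                "weighted_degree": result.weighted_degree(node),
                "degree": result.subgraph.degree(node),
                "seeds_in_component": len(comp & seeds),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["gene_symbol", "weighted_degree", "degree", "seeds_in_component"]
        )
    df = pd.DataFrame(rows).sort_values(
        ["weighted_degree", "degree", "gene_symbol"],
        ascending=[False, False, True],
    )
    return df.reset_index(drop=True)


def seed_component_report(result: ExpansionResult) -> pd.DataFrame:
    """Connected components of the expanded subgraph with seed counts.

    Flags seeds isolated from the largest seed-bearing component.
    """
    seeds = set(result.seeds)
    rows = []
    for i, comp in enumerate(
        sorted(result.components, key=lambda c: (-len(c), sorted(c)[0]))
    ):
        rows.append(
            {
                "component": i,
                "size": len(comp),
                "n_seeds": len(comp & seeds),
                "seed_members": ",".join(sorted(comp & seeds)),
                "members": ",".join(sorted(comp)),
            }
        )
    df = pd.DataFrame(rows)
    seed_bearing = df[df["n_seeds"] > 0]
    if len(seed_bearing) > 1:
        main = seed_bearing.iloc[0]
        stray = seed_bearing.iloc[1:]["seed_members"].tolist()
        logger.info(
            "seeds outside the main component (%d seeds): %s",
            int(main["n_seeds"]),
            "; ".join(stray),
        )
    return df
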