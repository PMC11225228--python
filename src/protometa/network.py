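"""Bipartite metabolite-enzyme reaction networks.

A reaction network is a directed bipartite graph: reactant edges run
metabolite -> enzyme and product edges enzyme -> metabolite, each tagged
with a reaction id.  A reaction may be flagged "reverse" (annotated against
its physiological direction), which downstream imbalance scoring uses to
flip the sign of its score.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import networkx as nx

NODE_KINDS = ("metabolite", "enzyme")


class NetworkFormatError(ValueError):
    pass


@dataclass
class ReactionNetwork:
    graph: nx.DiGraph  # node attr 'kind'; edge attr 'reaction'
    reverse: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        reactants: dict[str, list] = {}
        products: dict[str, list] = {}
        for node, attrs in self.graph.nodes(data=True):
            if attrs.get("kind") not in NODE_KINDS:
                raise NetworkFormatError(f"node {node!r} has no metabolite/enzyme kind")
        for u, v, attrs in self.graph.edges(data=True):
            ku = self.graph.nodes[u]["kind"]
            kv = self.graph.nodes[v]["kind"]
            if ku == kv:
                raise NetworkFormatError(
                    f"edge {u!r} -> {v!r} links two {ku} nodes; the network must "
                    "be bipartite"
                )
            rid = attrs.get("reaction")
            if rid is None:
                raise NetworkFormatError(f"edge {u!r} -> {v!r} lacks a reaction id")
            if ku == "metabolite":
                reactants.setdefault(rid, []).append(u)
            else:
                products.setdefault(rid, []).append(v)
        for rid in set(reactants) | set(products):
            if rid not in reactants:
                raise NetworkFormatError(f"reaction {rid!r} has no reactant edge")
            if rid not in products:
                raise NetworkFormatError(f"reaction {rid!r} has no product edge")
            self.reverse.setdefault(rid, False)

    @property
    def metabolites(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "metabolite"]

    @property
    def enzymes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "enzyme"]

    def reactions_of(self, enzyme: str) -> list[str]:
        rids = set()
        for _, _, attrs in self.graph.in_edges(enzyme, data=True):
            rids.add(attrs["reaction"])
        for _, _, attrs in self.graph.out_edges(enzyme, data=True):
            rids.add(attrs["reaction"])
        return sorted(rids)

    def reactants(self, enzyme: str, reaction: str) -> list:
        return sorted(
            u
            for u, _, a in self.graph.in_edges(enzyme, data=True)
            if a["reaction"] == reaction
        )

    def products(self, enzyme: str, reaction: str) -> list:
        return sorted(
            v
            for _, v, a in self.graph.out_edges(enzyme, data=True)
            if a["reaction"] == reaction
        )

    def adjacent_metabolites(self, enzyme: str) -> set:
        mets = {u for u, _ in self.graph.in_edges(enzyme)}
        mets |= {v for _, v in self.graph.out_edges(enzyme)}
        return mets


def from_edges(
    edges: list[tuple[str, str, str]],
    node_kinds: dict[str, str],
    reverse: dict[str, bool] | None = None,
) -> ReactionNetwork:
    """Build a network from (source, target, reaction_id) triples."""
    g = nx.DiGraph()
    for node, kind in node_kinds.items():
        g.add_node(node, kind=kind)
    for u, v, rid in edges:
        for n in (u, v):
            if n not in g:
                raise NetworkFormatError(f"edge references untyped node {n!r}")
        g.add_edge(u, v, reaction=rid)
    return ReactionNetwork(graph=g, reverse=dict(reverse or {}))


def read_network(path) -> ReactionNetwork:
    """Read a TSV edge list: source, target, reaction_id, reverse,
    source_type, target_type."""
    required = ["source", "target", "reaction_id", "reverse", "source_type", "target_type"]
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in required):
            raise NetworkFormatError(
                f"{path}: expected columns {required}, got {reader.fieldnames}"
            )
        edges, kinds, reverse = [], {}, {}
        for row in reader:
            for node, kind in ((row["source"], row["source_type"]), (row["target"], row["target_type"])):
                if kinds.get(node, kind) != kind:
                    raise NetworkFormatError(f"{path}: node {node!r} has conflicting types")
                kinds[node] = kind
            rid = row["reaction_id"]
            rev = row["reverse"].strip().lower() in ("1", "true", "yes")
            if reverse.setdefault(rid, rev) != rev:
                raise NetworkFormatError(f"{path}: reaction {rid!r} has conflicting reverse flags")
            edges.append((row["source"], row["target"], rid))
    return from_edges(edges, kinds, reverse)


def write_network(net: ReactionNetwork, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["source", "target", "reaction_id", "reverse", "source_type", "target_type"])
        for u, v, attrs in sorted(net.graph.edges(data=True)):
            rid = attrs["reaction"]
            writer.writerow(
                [
                    u,
                    v,
                    rid,
                    str(net.reverse.get(rid, False)).lower(),
                    net.graph.nodes[u]["kind"],
                    net.graph.nodes[v]["kind"],
                ]
            )
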