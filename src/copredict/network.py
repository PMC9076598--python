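"""Co-prediction rule networks.

One network per decision class: nodes are descriptors (gene, discretized
level), edges connect descriptors co-occurring in the IF-part of a kept
rule.  A gene may therefore appear with one level in the low-activity
network and a different level in the high-activity one.  Edge strength
("connection") sums coverage*accuracy over the shared rules and is
max-normalized to percent within each class network; node size carries
the number of supporting objects, node border the number of rules.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .rules import Descriptor, Rule


@dataclass
class RuleNetwork:
    """Per-class descriptor graph with Fig-style node/edge attributes."""

    decision: str
    nodes: dict[Descriptor, dict] = field(default_factory=dict)
    # unordered descriptor pair -> {"connection", "normalized_connection"}
    edges: dict[tuple[Descriptor, Descriptor], dict] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        # the per-node rule-string lists are working state, not part of the
        # serialized identity of a network
        if not isinstance(other, RuleNetwork):
            return NotImplemented

        def strip(nodes):
            return {
                d: {"n_objects": a["n_objects"], "n_rules": a["n_rules"],
                    "cluster_composition": a.get("cluster_composition", {})}
                for d, a in nodes.items()
            }

        return (self.decision == other.decision
                and strip(self.nodes) == strip(other.nodes)
                and self.edges == other.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _edge_key(a: Descriptor, b: Descriptor) -> tuple[Descriptor, Descriptor]:
    return (a, b) if a <= b else (b, a)


def build_network(rules: list[Rule], decision: str,
                  min_support_frac: float = 0.10,
                  alpha: float = 0.05) -> RuleNetwork:
    """Build the co-prediction network of one decision class.

    Keeps rules of the class with coverage >= ``min_support_frac`` and
    p_value <= ``alpha``.  Edge connection = sum over shared kept rules of
    coverage*accuracy, normalized so the strongest edge in the class
    network is 100.  A filter that keeps no rule yields an empty network.
    """
    kept = [r for r in rules
            if r.decision == decision
            and r.coverage >= min_support_frac
            and r.p_value <= alpha]
    net = RuleNetwork(decision=decision)
    node_rules: dict[Descriptor, list[Rule]] = {}
    for r in kept:
        for d in r.lhs:
            node_rules.setdefault(d, []).append(r)
    for d, rs in node_rules.items():
        support_union: set[str] = set()
        for r in rs:
            support_union |= r.support_set
        net.nodes[d] = {
            "n_objects": len(support_union),
            "n_rules": len(rs),
            "rules": [str(r) for r in rs],
        }
    for r in kept:
        w = r.coverage * r.accuracy
        for a, b in itertools.combinations(sorted(r.lhs), 2):
            key = _edge_key(a, b)
            e = net.edges.setdefault(key, {"connection": 0.0})
            e["connection"] += w
    if net.edges:
        cmax = max(e["connection"] for e in net.edges.values())
        for e in net.edges.values():
            e["normalized_connection"] = 100.0 * e["connection"] / cmax
    return net


def project_clusters(network: RuleNetwork,
                     rule_to_cluster: dict[str, set] | dict[str, list]) -> dict[Descriptor, dict]:
    """Per-node cluster composition: the fraction of the node's kept rules
    belonging to each cluster (a rule in several clusters contributes to
    each; rules in no cluster count as "unassigned").  Fractions are
    stored on the nodes under ``cluster_composition`` and returned."""
    out: dict[Descriptor, dict] = {}
    for d, attrs in network.nodes.items():
        counts: dict[str, float] = {}
        n = 0
        for rule_str in attrs["rules"]:
            clusters = rule_to_cluster.get(rule_str)
            if not clusters:
                members = ["unassigned"]
            else:
                members = sorted(str(c) for c in clusters)
            n += 1
            for c in members:
                counts[c] = counts.get(c, 0.0) + 1.0 / len(members)
        comp = {c: v / n for c, v in counts.items()} if n else {}
        attrs["cluster_composition"] = comp
        out[d] = comp
    return out


def export_network(network: RuleNetwork, path: str | Path,
                   fmt: str = "graphml") -> Path:
    """Write a network as GraphML (node/edge attributes preserved) or as a
    flat TSV edge list with a node table header block."""
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph(decision=network.decision)
        for d, attrs in network.nodes.items():
            g.add_node(str(d), gene=d.gene, level=int(d.level),
                       n_objects=int(attrs["n_objects"]),
                       n_rules=int(attrs["n_rules"]),
                       cluster_composition=json.dumps(
                           attrs.get("cluster_composition", {}), sort_keys=True))
        for (a, b), e in network.edges.items():
            g.add_edge(str(a), str(b),
                       connection=float(e["connection"]),
                       normalized_connection=float(e["normalized_connection"]))
        nx.write_graphml(g, path)
    elif fmt == "edge-tsv":
        rows = []
        for (a, b), e in sorted(network.edges.items()):
            rows.append({"decision": network.decision,
                         "source": str(a), "target": str(b),
                         "connection": repr(float(e["connection"])),
                         "normalized_connection": repr(float(e["normalized_connection"]))})
        pd.DataFrame(rows, columns=["decision", "source", "target",
                                    "connection", "normalized_connection"]
                     ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    return path


def _parse_descriptor(s: str) -> Descriptor:
    gene, level = s.rsplit("=", 1)
    return Descriptor(gene, int(level))


def read_network(path: str | Path, fmt: str = "graphml") -> RuleNetwork:
    """Read back a network written by :func:`export_network`.

    The GraphML round trip restores node and edge attributes (the per-node
    rule lists are not serialized); the TSV round trip restores edges only.
    """
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        net = RuleNetwork(decision=g.graph.get("decision", ""))
        for n, attrs in g.nodes(data=True):
            d = _parse_descriptor(n)
            net.nodes[d] = {
                "n_objects": int(attrs["n_objects"]),
                "n_rules": int(attrs["n_rules"]),
                "cluster_composition": json.loads(
                    attrs.get("cluster_composition", "{}")),
            }
        for a, b, attrs in g.edges(data=True):
            key = _edge_key(_parse_descriptor(a), _parse_descriptor(b))
            net.edges[key] = {
                "connection": float(attrs["connection"]),
                "normalized_connection": float(attrs["normalized_connection"]),
            }
        return net
    if fmt == "edge-tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        decision = str(df["decision"].iloc[0]) if len(df) else ""
        net = RuleNetwork(decision=decision)
        for _, row in df.iterrows():
            key = _edge_key(_parse_descriptor(row["source"]),
                            _parse_descriptor(row["target"]))
            net.edges[key] = {
                "connection": float(row["connection"]),
                "normalized_connection": float(row["normalized_connection"]),
            }
        return net
    raise ValueError(f"unknown network format {fmt!r}")
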