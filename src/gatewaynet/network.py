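"""Gateway networks: weighted digraphs of initiation rules, exported as DOT.

Vertices are events (or itemset junction nodes for higher-degree rules) and
each rule contributes one edge carrying its support (drawn as pen width) and
its certainty (drawn as a white-to-blue log-scaled gradient for gateway
edges).  Three render modes exist: ``plain`` (uniform styling), ``highlight``
(gateway edges colored, the rest gray) and ``gateway_only`` (non-gateway edges
and the vertices they orphan removed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx

from .irm import RuleSet, InitiationRule

__all__ = ["GatewayNetwork", "build_network", "to_dot", "certainty_color", "MODES"]

logger = logging.getLogger(__name__)

MODES = ("plain", "highlight", "gateway_only")

#: gradient endpoints: white -> saturated blue
_COLOR_LO = (255, 255, 255)
_COLOR_HI = (0, 0, 255)


def _node_id(itemset: frozenset) -> str:
    labels = sorted(itemset)
    return labels[0] if len(labels) == 1 else "{" + ",".join(labels) + "}"


@dataclass(frozen=True)
class GatewayNetwork:
    """A weighted digraph wrapper around :class:`networkx.DiGraph`.

    Rule edges carry ``weight`` (support), ``certainty`` and ``gateway``
    attributes; junction *member* edges (linking a multi-event itemset node to
    its constituent events) carry ``kind="member"``.
    """

    graph: nx.DiGraph

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def rule_edges(self) -> list[tuple[str, str, dict]]:
        return sorted(
            (u, v, d) for u, v, d in self.graph.edges(data=True) if d.get("kind") == "rule"
        )


def build_network(rules: RuleSet) -> GatewayNetwork:
    """Assemble the digraph for a mined rule set.

    Degree-1 rules become direct edges between single-event vertices.  A
    multi-event antecedent or subsequent is rendered through a junction vertex
    labeled with the joined itemset, tied to its constituent events by
    unweighted member edges (inbound for antecedents, outbound for
    subsequents).  When several rules map to the same (source, target) pair,
    the one with maximal certainty wins and the collision is logged.
    """
    g = nx.DiGraph()
    for rule in rules:
        src, dst = rule.antecedent, rule.subsequent
        src_id, dst_id = _node_id(src), _node_id(dst)
        for itemset, nid in ((src, src_id), (dst, dst_id)):
            g.add_node(nid, label=nid, junction=len(itemset) > 1)
            if len(itemset) > 1:
                for member in sorted(itemset):
                    g.add_node(member, label=member, junction=False)
        if len(src) > 1:
            for member in sorted(src):
                if not g.has_edge(member, src_id):
                    g.add_edge(member, src_id, kind="member")
        if len(dst) > 1:
            for member in sorted(dst):
                if not g.has_edge(dst_id, member):
                    g.add_edge(dst_id, member, kind="member")
        if g.has_edge(src_id, dst_id) and g[src_id][dst_id].get("kind") == "rule":
            old = g[src_id][dst_id]
            if old["certainty"] >= rule.certainty:
                logger.warning("edge %s -> %s already present with certainty %s; keeping it",
                               src_id, dst_id, old["certainty"])
                continue
            logger.warning("edge %s -> %s replaced by higher-certainty rule (%s -> %s)",
                           src_id, dst_id, old["certainty"], rule.certainty)
        g.add_edge(src_id, dst_id, kind="rule", weight=rule.support,
                   certainty=rule.certainty, gateway=rule.is_gateway)
    return GatewayNetwork(g)


def certainty_color(cert: float, c_min: float, c_max: float) -> str:
    """Hex color for a certainty on a log-scaled white-to-blue ramp.

    ``log10(cert)`` is clamped to ``[log10 c_min, log10 c_max]`` and mapped
    linearly onto the gradient; +inf saturates at the top color.
    """
    if not c_min < c_max:
        raise ValueError("c_min must be < c_max")
    if c_min <= 0:
        raise ValueError("gradient bounds must be positive")
    if cert <= 0:
        raise ValueError("certainty must be positive for color mapping")
    if math.isinf(cert):
        frac = 1.0
    else:
        lo, hi = math.log10(c_min), math.log10(c_max)
        frac = (min(max(math.log10(cert), lo), hi) - lo) / (hi - lo)
    rgb = tuple(round(a + frac * (b - a)) for a, b in zip(_COLOR_LO, _COLOR_HI))
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def _fmt(x: float) -> str:
    return "inf" if math.isinf(x) else f"{x:.6g}"


def _gradient_bounds(net: GatewayNetwork, l_cert: float) -> tuple[float, float]:
    finite = sorted(
        d["certainty"]
        for _, _, d in net.graph.edges(data=True)
        if d.get("kind") == "rule" and d["certainty"] > l_cert and math.isfinite(d["certainty"])
    )
    if len(finite) >= 2 and finite[0] < finite[-1]:
        return finite[0], finite[-1]
    # degenerate spread: anchor the ramp at the gateway cutoff
    return l_cert, l_cert * 100.0


def to_dot(net: GatewayNetwork, mode: str = "plain", l_cert: float = 1.0) -> str:
    """Serialize the network as a deterministic GraphViz ``digraph`` document.

    Edge pen width grows linearly with rule support; in ``highlight`` mode
    gateway edges (certainty > ``l_cert``) are colored by
    :func:`certainty_color` and the rest are gray; ``gateway_only`` drops
    non-gateway rule edges, member edges of dropped junctions, and any vertex
    left without incident edges.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    g = net.graph
    c_min, c_max = _gradient_bounds(net, l_cert)

    def is_gateway(d: dict) -> bool:
        return d.get("kind") == "rule" and d["certainty"] > l_cert

    edges = sorted(g.edges(data=True), key=lambda e: (e[0], e[1]))
    if mode == "gateway_only":
        kept_rule = [(u, v, d) for u, v, d in edges if is_gateway(d)]
        kept_nodes = {u for u, _, _ in kept_rule} | {v for _, v, _ in kept_rule}
        members = [
            (u, v, d) for u, v, d in edges
            if d.get("kind") == "member" and (u in kept_nodes or v in kept_nodes)
        ]
        edges = sorted(kept_rule + members, key=lambda e: (e[0], e[1]))
        nodes = sorted({u for u, _, _ in edges} | {v for _, v, _ in edges})
    else:
        nodes = sorted(g.nodes)

    lines = ["digraph gateway_network {"]
    for n in nodes:
        attrs = ['label="{}"'.format(n)]
        if g.nodes[n].get("junction"):
            attrs.append("shape=box")
            attrs.append("style=dashed")
        lines.append(f'  "{n}" [{", ".join(attrs)}];')
    for u, v, d in edges:
        if d.get("kind") == "member":
            lines.append(f'  "{u}" -> "{v}" [style=dotted, arrowhead=none];')
            continue
        attrs = [f"penwidth={1.0 + 4.0 * d['weight']:.3f}",
                 f'label="{_fmt(d["weight"])}"']
        if mode == "plain":
            attrs.append('color="#000000"')
        elif is_gateway(d):
            attrs.append(f'color="{certainty_color(d["certainty"], c_min, c_max)}"')
        else:
            attrs.append('color="#B0B0B0"')
        lines.append(f'  "{u}" -> "{v}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
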