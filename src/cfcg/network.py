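"""Component–target network construction and topology.

The component–target (C-T) network is an undirected bipartite graph whose
one side is chemical components and whose other side is their protein/gene
targets.  The converged network additionally carries protein–protein
interaction (PPI) edges between targets already present in the C-T
network.  Degree and eccentricity of these graphs feed the contribution
model and the knapsack selection.

All graphs are simple, undirected and unweighted.  Eccentricity is taken
within a node's connected component (the NetworkAnalyzer convention for
disconnected graphs); an isolated node has eccentricity 0.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import networkx as nx
from scipy import stats

from .io_core import ComponentRecord, EdgeTable

__all__ = [
    "BipartiteCTNetwork",
    "ConvergedNetwork",
    "build_ct_network",
    "herb_subnetwork",
    "converge_with_ppi",
    "node_eccentricity",
    "all_eccentricities",
    "median_degree_filter",
    "compare_degree_groups",
]

log = logging.getLogger(__name__)

COMPONENT = "component"
TARGET = "target"


@dataclass
class BipartiteCTNetwork:
    """Bipartite component–target graph.

    ``graph`` nodes carry a ``kind`` attribute ("component" or "target");
    components also carry their record's herb set for subnetwork queries.
    """

    graph: nx.Graph

    @property
    def components(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == COMPONENT)

    @property
    def targets(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == TARGET)

    def targets_of(self, component_id: str) -> list[str]:
        return sorted(self.graph.neighbors(component_id))

    def degree(self, node: str) -> int:
        return self.graph.degree(node)


@dataclass
class ConvergedNetwork(BipartiteCTNetwork):
    """C-T network merged with PPI edges among its existing targets."""

    n_ppi_added: int = 0
    n_ppi_dropped: int = 0
    ct_graph: nx.Graph = field(default_factory=nx.Graph)

    def targets_of(self, component_id: str) -> list[str]:
        # component neighbourhood is defined by C-T edges only
        return sorted(self.ct_graph.neighbors(component_id))


def build_ct_network(
    components: list[ComponentRecord], ct_edges: EdgeTable
) -> BipartiteCTNetwork:
    """Build the bipartite graph from records and a component→target edge list.

    Target nodes are created from the edges; every edge source must be a
    known component id, otherwise all offenders are reported at once.
    """
    g = nx.Graph()
    herb_of = {}
    for rec in components:
        g.add_node(rec.component_id, kind=COMPONENT, herbs=rec.herbs)
        herb_of[rec.component_id] = rec.herbs
    unknown = sorted({c for c, _ in ct_edges.edges if c not in herb_of})
    if unknown:
        raise ValueError(f"edges reference unknown component id(s): {', '.join(unknown)}")
    for comp, tgt in ct_edges.edges:
        if tgt not in g:
            g.add_node(tgt, kind=TARGET)
        elif g.nodes[tgt]["kind"] == COMPONENT:
            raise ValueError(f"edge endpoint {tgt!r} is a component, expected a target")
        g.add_edge(comp, tgt)
    return BipartiteCTNetwork(graph=g)


def herb_subnetwork(net: BipartiteCTNetwork, herb: str) -> BipartiteCTNetwork:
    """Induced subgraph on one herb's components plus their targets."""
    all_herbs = set()
    for _, d in net.graph.nodes(data=True):
        if d["kind"] == COMPONENT:
            all_herbs |= set(d["herbs"])
    if herb not in all_herbs:
        raise ValueError(f"unknown herb {herb!r}; known: {', '.join(sorted(all_herbs))}")
    comps = [
        n for n, d in net.graph.nodes(data=True)
        if d["kind"] == COMPONENT and herb in d["herbs"]
    ]
    nodes = set(comps)
    for c in comps:
        nodes.update(net.graph.neighbors(c))
    return BipartiteCTNetwork(graph=net.graph.subgraph(nodes).copy())


def converge_with_ppi(net: BipartiteCTNetwork, ppi_edges: EdgeTable) -> ConvergedNetwork:
    """Merge PPI edges among existing target nodes into the C-T network.

    PPI edges touching a node absent from the C-T network (or a component
    node) are dropped; the count of dropped edges is logged and recorded.
    """
    g = net.graph.copy()
    targets = {n for n, d in g.nodes(data=True) if d["kind"] == TARGET}
    added = dropped = 0
    for a, b in ppi_edges.edges:
        if a in targets and b in targets and a != b:
            if not g.has_edge(a, b):
                g.add_edge(a, b)
                added += 1
        else:
            dropped += 1
    if dropped:
        log.info("converge_with_ppi: dropped %d PPI edge(s) outside the target set", dropped)
    return ConvergedNetwork(
        graph=g, n_ppi_added=added, n_ppi_dropped=dropped, ct_graph=net.graph.copy()
    )


def node_eccentricity(net: BipartiteCTNetwork, node: str) -> int:
    """Maximum shortest-path length from ``node`` to any reachable node.

    Computed within the node's connected component; an isolated node has
    eccentricity 0.
    """
    if node not in net.graph:
        raise ValueError(f"unknown node {node!r}")
    lengths = nx.single_source_shortest_path_length(net.graph, node)
    return max(lengths.values())


def all_eccentricities(net: BipartiteCTNetwork) -> dict[str, int]:
    """Eccentricity of every node (per connected component)."""
    out: dict[str, int] = {}
    for comp_nodes in nx.connected_components(net.graph):
        sub = net.graph.subgraph(comp_nodes)
        if len(comp_nodes) == 1:
            out[next(iter(comp_nodes))] = 0
        else:
            out.update(nx.eccentricity(sub))
    return out


def median_degree_filter(
    conv: BipartiteCTNetwork, components: list[str], targets: list[str]
) -> tuple[set[str], float]:
    """Retain targets whose degree strictly exceeds the pooled median.

    The median is computed over the pooled degree list of *all* listed
    targets and components together (lower+upper midpoint for even pools);
    only targets can be retained.  Returns (retained set, median).
    """
    pool = [conv.degree(n) for n in list(components) + list(targets)]
    if not pool:
        raise ValueError("median_degree_filter: empty component+target pool")
    m = statistics.median(pool)
    retained = {t for t in targets if conv.degree(t) > m}
    if not retained:
        log.warning("median_degree_filter: no target exceeds the median degree %.1f", m)
    return retained, m


def compare_degree_groups(group_a, group_b) -> tuple[float, int, float]:
    """Student's (pooled-variance) two-sample t-test on two degree lists.

    Returns (t, degrees of freedom, two-sided p).  Two groups with zero
    pooled variance and equal means give (0, df, 1) by convention; zero
    variance with unequal means is an error (the statistic is undefined).
    """
    a = [float(x) for x in group_a]
    b = [float(x) for x in group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    df = len(a) + len(b) - 2
    var_a = statistics.variance(a)
    var_b = statistics.variance(b)
    if var_a == 0 and var_b == 0:
        if statistics.mean(a) == statistics.mean(b):
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)
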