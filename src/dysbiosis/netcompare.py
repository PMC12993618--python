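"""Summaries and contrasts of two condition-specific co-occurrence networks.

Covers the lesion vs peri-lesion questions: how many (connected) nodes and
edges each network has, which taxa gained or lost degree between conditions,
which taxa are hubs, and how quickly each network's largest connected
component (LCC) collapses under node removal. Fragility is quantified as
one minus the area under the LCC-fraction curve as nodes are removed —
either highest-degree-first (targeted attack) or in random order averaged
over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import CooccurrenceNetwork


@dataclass
class NetworkSummary:
    """Headline figures for one network.

    ``n_nodes`` counts connected (non-isolated) nodes — the convention used
    when two networks over the same taxon set differ in node count;
    ``n_nodes_total`` includes orphans.
    """

    n_nodes: int
    n_nodes_total: int
    n_edges: int
    mean_degree: float
    degree_sequence: list[int]


@dataclass
class DegreeComparison:
    """Per-taxon degree in two networks over the union of their node sets."""

    table: pd.DataFrame  # index taxon; columns degree_a, degree_b, in_a, in_b, change
    n_decreased: int
    n_increased: int
    n_unchanged: int
    hubs_a: list[tuple[str, int]]
    hubs_b: list[tuple[str, int]]


@dataclass
class RobustnessCurve:
    """LCC decay under node removal and the derived fragility index."""

    strategy: str
    fractions_removed: np.ndarray
    lcc_fractions: np.ndarray
    auc: float
    fragility: float
    n_random_reps: int = 0
    seed: int | None = None


def _graph_of(net) -> nx.Graph:
    return net.graph if isinstance(net, CooccurrenceNetwork) else net


def summarize(network) -> NetworkSummary:
    """Node/edge counts, mean degree and the degree sequence."""
    g = _graph_of(network)
    degrees = dict(g.degree())
    non_isolated = [n for n, d in degrees.items() if d > 0]
    n_edges = g.number_of_edges()
    mean_deg = 2 * n_edges / len(non_isolated) if non_isolated else 0.0
    return NetworkSummary(
        n_nodes=len(non_isolated),
        n_nodes_total=g.number_of_nodes(),
        n_edges=n_edges,
        mean_degree=mean_deg,
        degree_sequence=sorted(degrees.values(), reverse=True),
    )


def compare_degrees(net_a, net_b, top_k: int = 10) -> DegreeComparison:
    """Join per-taxon degrees of two networks; absent taxa get degree 0.

    Also reports the top-``top_k`` hubs of each network so statements like
    "taxon X lost most of its connections in condition A" can be read off
    mechanically.
    """
    ga, gb = _graph_of(net_a), _graph_of(net_b)
    union = sorted(set(ga.nodes) | set(gb.nodes))
    rows = []
    for t in union:
        da = ga.degree(t) if t in ga else 0
        db = gb.degree(t) if t in gb else 0
        change = "decreased" if da < db else ("increased" if da > db else "unchanged")
        rows.append((t, da, db, t in ga, t in gb, change))
    df = pd.DataFrame(
        rows, columns=["taxon", "degree_a", "degree_b", "in_a", "in_b", "change"]
    ).set_index("taxon")

    def hubs(g):
        ranked = sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))
        return [(t, d) for t, d in ranked[:top_k] if d > 0]

    counts = df["change"].value_counts()
    return DegreeComparison(
        table=df,
        n_decreased=int(counts.get("decreased", 0)),
        n_increased=int(counts.get("increased", 0)),
        n_unchanged=int(counts.get("unchanged", 0)),
        hubs_a=hubs(ga),
        hubs_b=hubs(gb),
    )


def _lcc_size(g: nx.Graph) -> int:
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(g))


def _attack_curve(g: nx.Graph, order: list[str], n0: int) -> np.ndarray:
    """LCC fraction (of the initial non-isolated count) after each removal."""
    h = g.copy()
    out = np.empty(len(order))
    for k, node in enumerate(order):
        h.remove_node(node)
        out[k] = _lcc_size(h) / n0 if h.number_of_nodes() else 0.0
    return out


def robustness(
    network,
    strategy: str = "targeted_degree",
    n_random_reps: int = 100,
    seed: int = 0,
) -> RobustnessCurve:
    """LCC decay curve under node removal and fragility = 1 - AUC.

    ``targeted_degree`` removes the currently highest-degree node at each
    step (ties broken lexicographically by taxon id); ``random`` removes
    nodes in uniformly random order and averages the curve over
    ``n_random_reps`` replicates. Only the initially non-isolated nodes are
    attacked; the curve starts at (0, LCC0/n0) and the area under it is
    taken by the trapezoid rule over the fraction-removed grid.
    """
    g0 = _graph_of(network)
    non_isolated = sorted(n for n, d in g0.degree() if d > 0)
    n0 = len(non_isolated)
    if n0 < 2:
        raise ValueError("network needs at least 2 non-isolated nodes")
    g = g0.subgraph(non_isolated).copy()
    fractions = np.arange(n0 + 1) / n0
    start = _lcc_size(g) / n0

    if strategy == "targeted_degree":
        h = g.copy()
        curve = [start]
        while h.number_of_nodes():
            target = min(h.nodes, key=lambda t: (-h.degree(t), t))
            h.remove_node(target)
            curve.append(_lcc_size(h) / n0 if h.number_of_nodes() else 0.0)
        lcc = np.array(curve)
        reps, used_seed = 0, None
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        acc = np.zeros(n0)
        for _ in range(n_random_reps):
            order = list(rng.permutation(non_isolated))
            acc += _attack_curve(g, order, n0)
        lcc = np.concatenate([[start], acc / n_random_reps])
        reps, used_seed = n_random_reps, seed
    else:
        raise ValueError("strategy must be 'targeted_degree' or 'random'")

    auc = float(np.trapezoid(lcc, fractions))
    return RobustnessCurve(
        strategy=strategy,
        fractions_removed=fractions,
        lcc_fractions=lcc,
        auc=auc,
        fragility=1.0 - auc,
        n_random_reps=reps,
        seed=used_seed,
    )
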