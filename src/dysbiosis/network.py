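"""Co-occurrence network inference for compositional count data.

The pipeline follows the sparse inverse-covariance approach popular for 16S
data: counts are mapped out of the simplex with a centered log-ratio (CLR)
transform, conditional dependence is estimated by Meinshausen-Buhlmann
neighborhood selection (per-taxon L1-penalized regression) along a
log-spaced regularization path, and the penalty is chosen by StARS —
stability of edge selection across row subsamples. The result is an
undirected taxon graph whose edges carry their subsample selection
frequency as a stability score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.linear_model import lasso_path

from .data import TaxonCountTable

log = logging.getLogger(__name__)


@dataclass
class ClrMatrix:
    """Samples x taxa centered log-ratios; each row sums to zero."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    pseudocount: float = 1.0

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


@dataclass
class LambdaPath:
    """Decreasing penalty path with the adjacency estimate at each step."""

    lambdas: np.ndarray
    adjacency: np.ndarray  # (n_lambda, p, p) boolean, symmetric, zero diagonal
    rule: str = "or"

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.lambdas) < 0):
            raise ValueError("lambda path must be strictly decreasing")


@dataclass
class StarsResult:
    """Edge-selection frequencies and instability along the penalty path."""

    lambdas: np.ndarray
    frequencies: np.ndarray  # (n_lambda, p, p) selection frequency
    instability: np.ndarray
    instability_monotone: np.ndarray
    lambda_star: float
    lambda_star_index: int
    subsample_size: int
    n_reps: int
    beta: float
    seed: int


@dataclass
class CooccurrenceNetwork:
    """Undirected taxon graph with per-edge stability scores."""

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(u, v), max(u, v), d.get("stability", 1.0))
            for u, v, d in self.graph.edges(data=True)
        )

    @property
    def orphan_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.degree() if d == 0)


def clr_transform(table: TaxonCountTable, pseudocount: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform of pseudocounted counts.

    Per row: ``clr = log(counts + pseudocount) - mean(log(counts +
    pseudocount))``. Row sums are zero by construction.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = table.counts.astype(float) + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return ClrMatrix(
        list(table.sample_ids), list(table.taxon_ids), clr, pseudocount
    )


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score columns (population sd); returns (z, sd) with sd=0 kept as 0."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (x - mu) / safe, sd


def lambda_path_values(
    values: np.ndarray, n_lambda: int = 20, lambda_min_ratio: float = 0.01
) -> np.ndarray:
    """Log-spaced penalty path from the largest absolute column correlation."""
    z, sd = _standardize(values)
    n = z.shape[0]
    corr = z.T @ z / n
    np.fill_diagonal(corr, 0.0)
    lam_max = float(np.abs(corr).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def mb_path(
    clr: ClrMatrix | np.ndarray,
    n_lambda: int = 20,
    lambda_min_ratio: float = 0.01,
    rule: str = "or",
    lambdas: np.ndarray | None = None,
) -> LambdaPath:
    """Neighborhood-selection graph estimates along a penalty path.

    For every taxon ``j``, its standardized CLR column is lasso-regressed on
    all other standardized columns at each penalty; an edge (i, j) is present
    when either regression selects the other taxon (OR rule, the default) or
    when both do (AND rule). Constant columns are excluded with a warning.
    """
    values = clr.values if isinstance(clr, ClrMatrix) else np.asarray(clr)
    n, p = values.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 samples and 2 taxa")
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    if lambdas is None:
        lambdas = lambda_path_values(values, n_lambda, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)

    z, sd = _standardize(values)
    active = np.flatnonzero(sd > 0)
    if active.size < p:
        warnings.warn(
            f"{p - active.size} constant column(s) excluded from regressions"
        )
    k = len(lambdas)
    selected = np.zeros((k, p, p), dtype=bool)  # selected[l, j, i]: i in nbhd(j)
    for j in active:
        others = active[active != j]
        if others.size == 0:
            continue
        _, coefs, _ = lasso_path(z[:, others], z[:, j], alphas=lambdas)
        nz = np.abs(coefs) > 1e-10  # (n_others, n_lambda)
        for li in range(k):
            selected[li, j, others[nz[:, li]]] = True
    if rule == "or":
        adj = selected | selected.transpose(0, 2, 1)
    else:
        adj = selected & selected.transpose(0, 2, 1)
    for li in range(k):
        np.fill_diagonal(adj[li], False)
    return LambdaPath(lambdas=lambdas, adjacency=adj, rule=rule)


def stars_select(
    clr: ClrMatrix,
    n_lambda: int = 20,
    lambda_min_ratio: float = 0.01,
    n_reps: int = 50,
    beta: float = 0.05,
    seed: int = 0,
    rule: str = "or",
    subsample_size: int | None = None,
) -> StarsResult:
    """StARS penalty selection over row subsamples.

    Draws ``n_reps`` subsamples without replacement of size
    ``b = min(floor(10 * sqrt(n)), floor(0.8 * n))``, re-estimates the graph
    on each, and summarizes per-edge selection frequencies theta into the
    instability ``D(lambda) = mean over pairs of 2 * theta * (1 - theta)``.
    D is monotonized from the sparse (large-penalty) end by a running
    maximum; the selected penalty is the smallest lambda whose monotonized
    instability stays within ``beta``. If no penalty qualifies the densest
    one is returned with a warning.
    """
    n, p = clr.values.shape
    if n < 10:
        raise ValueError("StARS needs at least 10 samples")
    lambdas = lambda_path_values(clr.values, n_lambda, lambda_min_ratio)
    b = subsample_size or min(int(10 * np.sqrt(n)), int(0.8 * n))
    b = min(b, n)
    rng = np.random.default_rng(seed)
    k = len(lambdas)
    freq = np.zeros((k, p, p))
    for _ in range(n_reps):
        rows = (
            np.arange(n) if b == n else rng.choice(n, size=b, replace=False)
        )
        sub = mb_path(clr.values[rows], rule=rule, lambdas=lambdas)
        freq += sub.adjacency
    freq /= n_reps

    iu = np.triu_indices(p, 1)
    xi = 2.0 * freq * (1.0 - freq)
    instability = np.array([xi[li][iu].mean() for li in range(k)])
    monotone = np.maximum.accumulate(instability)
    ok = np.flatnonzero(monotone <= beta)
    if ok.size:
        idx = int(ok[-1])  # smallest qualifying lambda (path is decreasing)
    else:
        idx = k - 1
        warnings.warn(
            f"no penalty reached instability <= {beta}; using densest graph"
        )
    return StarsResult(
        lambdas=lambdas,
        frequencies=freq,
        instability=instability,
        instability_monotone=monotone,
        lambda_star=float(lambdas[idx]),
        lambda_star_index=idx,
        subsample_size=b,
        n_reps=n_reps,
        beta=beta,
        seed=seed,
    )


def build_network(
    path: LambdaPath,
    stars: StarsResult,
    taxa: list[str],
    provenance: dict | None = None,
) -> CooccurrenceNetwork:
    """Assemble the graph at the StARS-selected penalty.

    Edges come from the full-data path's adjacency at lambda*; each edge
    carries its subsample selection frequency as ``stability``. All filtered
    taxa enter as nodes; isolated ones are reported as orphans.
    """
    idx = stars.lambda_star_index
    adj = path.adjacency[idx]
    freq = stars.frequencies[idx]
    g = nx.Graph()
    g.add_nodes_from(taxa)
    p = len(taxa)
    for i in range(p):
        for j in range(i + 1, p):
            if adj[i, j]:
                g.add_edge(taxa[i], taxa[j], stability=float(freq[i, j]))
    prov = {
        "lambda_star": stars.lambda_star,
        "lambda_star_index": idx,
        "n_reps": stars.n_reps,
        "beta": stars.beta,
        "subsample_size": stars.subsample_size,
        "seed": stars.seed,
        "rule": path.rule,
    }
    if provenance:
        prov.update(provenance)
    return CooccurrenceNetwork(graph=g, provenance=prov)


def infer_network(
    table: TaxonCountTable,
    pseudocount: float = 1.0,
    n_lambda: int = 20,
    lambda_min_ratio: float = 0.01,
    n_reps: int = 50,
    beta: float = 0.05,
    seed: int = 0,
    rule: str = "or",
) -> CooccurrenceNetwork:
    """CLR -> MB path -> StARS -> network, end to end for one sample group."""
    clr = clr_transform(table, pseudocount=pseudocount)
    lambdas = lambda_path_values(clr.values, n_lambda, lambda_min_ratio)
    full = mb_path(clr, rule=rule, lambdas=lambdas)
    stars = stars_select(
        clr,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        n_reps=n_reps,
        beta=beta,
        seed=seed,
        rule=rule,
    )
    prov = {"pseudocount": pseudocount, "n_samples": clr.n_samples}
    return build_network(full, stars, clr.taxon_ids, provenance=prov)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def network_to_json(net: CooccurrenceNetwork) -> dict:
    return {
        "nodes": net.nodes,
        "edges": [
            {"u": u, "v": v, "stability": s} for u, v, s in net.edges
        ],
        "provenance": net.provenance,
    }


def network_from_json(doc: dict) -> CooccurrenceNetwork:
    g = nx.Graph()
    g.add_nodes_from(doc["nodes"])
    for e in doc["edges"]:
        g.add_edge(e["u"], e["v"], stability=e["stability"])
    return CooccurrenceNetwork(graph=g, provenance=doc.get("provenance", {}))


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
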