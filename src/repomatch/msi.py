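"""Multiscale-interactome diffusion profiles and mechanism subgraphs.

The interactome joins drugs, diseases, proteins and biological functions
with five undirected edge classes (drug–protein, disease–protein,
protein–protein, protein–function, function–function). A *diffusion
profile* is the stationary visitation distribution of a random walk with
restart from a drug or disease node, where at each step the walker either
restarts at the start node (probability ``1 − α``) or moves to a neighbour
chosen with probability proportional to a scalar weight attached to the
neighbour's node *type*:

    P(u → v) = w_type(v) / Σ_{v' ∈ N(u)} w_type(v')

Defaults follow the published optimisation of the method this module
implements: w_drug = 3.21, w_disease = 3.54, w_protein = 4.40,
w_function = 6.58, α = 0.859. The fixed point
``r = (1 − α)·e_start + α·Tᵀ·r`` is found by power iteration.

To explain how a drug might treat a disease, the top-k (default 10)
proteins and functions jointly prominent in the two profiles are selected
and every simple drug→disease path whose interior stays inside that set is
extracted as a mechanism subgraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "MSI_NODE_TYPES",
    "MSIParams",
    "DiffusionProfile",
    "MechanismSubgraph",
    "ConvergenceError",
    "build_msi_graph",
    "transition_operator",
    "diffusion_profile",
    "rank_relevant_nodes",
    "extract_mechanism_subgraph",
    "load_msi_tsv",
    "write_msi_tsv",
    "write_profile_tsv",
]

logger = logging.getLogger(__name__)

MSI_NODE_TYPES = ("drug", "disease", "protein", "biological_function")

#: undirected endpoint-type pairs an edge may join
ALLOWED_EDGE_CLASSES = frozenset(
    {
        frozenset({"disease", "protein"}),
        frozenset({"drug", "protein"}),
        frozenset({"protein"}),
        frozenset({"protein", "biological_function"}),
        frozenset({"biological_function"}),
    }
)


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance; carries the residual."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"diffusion profile did not converge within {max_iter} iterations "
            f"(residual {residual:.3e})"
        )
        self.residual = residual


@dataclass
class MSIParams:
    """Type weights, restart parameter and numerical controls.

    ``alpha`` is the probability of *continuing* the walk; ``k`` the number
    of top-ranked proteins/functions used for mechanism extraction.
    """

    w_drug: float = 3.21
    w_disease: float = 3.54
    w_protein: float = 4.40
    w_function: float = 6.58
    alpha: float = 0.859
    k: int = 10
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if min(self.w_drug, self.w_disease, self.w_protein, self.w_function) <= 0:
            raise ValueError("type weights must be positive")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")

    def weight_of(self, node_type: str) -> float:
        return {
            "drug": self.w_drug,
            "disease": self.w_disease,
            "protein": self.w_protein,
            "biological_function": self.w_function,
        }[node_type]


@dataclass
class DiffusionProfile:
    """Visitation distribution of a restart walk from one node."""

    start_node: str
    visitation: dict[str, float]

    def probability(self, node: str) -> float:
        return self.visitation.get(node, 0.0)


@dataclass
class MechanismSubgraph:
    """Union of the allowed drug→disease paths, for rendering."""

    drug: str
    disease: str
    allowed_nodes: set[str]
    paths: list[list[str]]
    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)


def build_msi_graph(
    node_types: Mapping[str, str], edges: Iterable[tuple[str, str]]
) -> nx.Graph:
    """Assemble and validate a typed interactome graph."""
    g = nx.Graph()
    for node, ntype in node_types.items():
        if ntype not in MSI_NODE_TYPES:
            raise ValueError(f"node {node!r} has unknown type {ntype!r}")
        g.add_node(node, type=ntype)
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        cls = frozenset({g.nodes[u]["type"], g.nodes[v]["type"]})
        if cls not in ALLOWED_EDGE_CLASSES:
            raise ValueError(
                f"edge {u!r}–{v!r} joins types {sorted(cls)}, which is not an "
                "allowed interactome edge class"
            )
        g.add_edge(u, v)
    return g


def transition_operator(
    graph: nx.Graph, params: MSIParams | None = None
) -> tuple[sparse.csr_matrix, list[str]]:
    """Row-stochastic type-biased transition matrix and its node order.

    From node ``u`` the step probability to neighbour ``v`` is
    ``w_type(v)`` normalised over all of ``u``'s neighbours. Rows of
    isolated nodes are zero (a walk may not start there). Rescaling all
    four weights by a common constant leaves the operator unchanged.
    """
    params = params or MSIParams()
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    order = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(order)}
    rows, cols, vals = [], [], []
    for u in order:
        nbrs = sorted(graph.neighbors(u))
        if not nbrs:
            continue
        weights = np.array([params.weight_of(graph.nodes[v]["type"]) for v in nbrs])
        probs = weights / weights.sum()
        rows.extend([index[u]] * len(nbrs))
        cols.extend(index[v] for v in nbrs)
        vals.extend(probs)
    n = len(order)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n)), order


def diffusion_profile(
    graph: nx.Graph, params: MSIParams | None = None, start: str | None = None
) -> DiffusionProfile:
    """Restart-walk visitation distribution from ``start``.

    Power iteration on ``r ← (1 − α)·e_start + α·Tᵀ·r`` from the uniform
    vector, stopping when the max-norm update falls below ``tol``.
    """
    params = params or MSIParams()
    if start is None or start not in graph:
        raise ValueError(f"start node {start!r} not in graph")
    if graph.degree(start) == 0:
        raise ValueError(f"start node {start!r} is isolated")
    t, order = transition_operator(graph, params)
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    e = np.zeros(n)
    e[index[start]] = 1.0
    tt = t.T.tocsr()
    r = np.full(n, 1.0 / n)
    residual = np.inf
    for _ in range(params.max_iter):
        r_next = (1.0 - params.alpha) * e + params.alpha * (tt @ r)
        residual = float(np.max(np.abs(r_next - r)))
        r = r_next
        if residual < params.tol:
            break
    else:
        raise ConvergenceError(residual, params.max_iter)
    visitation = {node: float(r[i]) for node, i in index.items() if r[i] > 0.0}
    return DiffusionProfile(start, visitation)


def rank_relevant_nodes(
    drug_profile: DiffusionProfile,
    disease_profile: DiffusionProfile,
    graph: nx.Graph,
    types: Sequence[str] = ("protein", "biological_function"),
    k: int = 10,
    combine: str = "geometric",
    per_type: bool = False,
) -> list[str]:
    """Top-k proteins/functions jointly prominent in both profiles.

    Combination rules: ``geometric`` (default — rewards nodes visited by
    both walks; a node visited by only one scores 0), ``arithmetic`` or
    ``minimum``. Ties break by node id. With ``per_type`` the top-k is
    taken within each requested type and concatenated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    combiners = {
        "geometric": lambda a, b: float(np.sqrt(a * b)),
        "arithmetic": lambda a, b: (a + b) / 2.0,
        "minimum": min,
    }
    if combine not in combiners:
        raise ValueError(f"unknown combination rule {combine!r}")
    fn = combiners[combine]

    def top(eligible: list[str]) -> list[str]:
        scored = [
            (
                -fn(drug_profile.probability(n), disease_profile.probability(n)),
                n,
            )
            for n in eligible
        ]
        scored.sort()
        return [n for _, n in scored[:k]]

    if per_type:
        out: list[str] = []
        for t in types:
            out.extend(top([n for n, d in graph.nodes(data=True) if d["type"] == t]))
        return out
    eligible = [n for n, d in graph.nodes(data=True) if d["type"] in set(types)]
    return top(sorted(eligible))


def extract_mechanism_subgraph(
    graph: nx.Graph,
    drug: str,
    disease: str,
    allowed_nodes: Iterable[str],
    max_path_length: int = 6,
) -> MechanismSubgraph:
    """All simple drug→disease paths whose interior stays in ``allowed_nodes``.

    Path length is counted in edges and capped at ``max_path_length``; the
    union of qualifying paths is returned as a subgraph for rendering. No
    qualifying path yields an empty subgraph with a warning.
    """
    for node in (drug, disease):
        if node not in graph:
            raise ValueError(f"node {node!r} not in graph")
    allowed = set(allowed_nodes)
    keep = allowed | {drug, disease}
    sub = graph.subgraph(keep)
    paths: list[list[str]] = []
    if drug in sub and disease in sub:
        paths = [
            list(p)
            for p in nx.all_simple_paths(sub, drug, disease, cutoff=max_path_length)
        ]
    paths.sort()
    result = MechanismSubgraph(drug, disease, allowed, paths)
    for p in paths:
        result.nodes.update(p)
        result.edges.update(
            tuple(sorted((a, b))) for a, b in zip(p, p[1:])
        )
    if not paths:
        logger.warning(
            "no path of length <= %d between %s and %s inside the allowed set",
            max_path_length,
            drug,
            disease,
        )
    return result


# ---------------------------------------------------------------------------
# I/O


def load_msi_tsv(path: str | Path) -> nx.Graph:
    """Load the typed 5-column edge-list dialect (types restricted to MSI)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    node_types: dict[str, str] = {}
    for _, row in table.iterrows():
        node_types[row.source_id] = row.source_type
        node_types[row.target_id] = row.target_type
    edges = [(r.source_id, r.target_id) for r in table.itertuples()]
    return build_msi_graph(node_types, edges)


def load_msi_edgelists(paths_by_class: Mapping[str, str | Path]) -> nx.Graph:
    """Load the two-column per-edge-class layout of the public release.

    ``paths_by_class`` maps a class name like ``"drug-protein"`` (first
    type is the first column) to a headerless two-column TSV.
    """
    node_types: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    for cls, path in sorted(paths_by_class.items()):
        t1, t2 = cls.split("-")
        t1 = "biological_function" if t1 == "function" else t1
        t2 = "biological_function" if t2 == "function" else t2
        table = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
        for row in table.itertuples():
            node_types.setdefault(row.a, t1)
            node_types.setdefault(row.b, t2)
            edges.append((row.a, row.b))
    return build_msi_graph(node_types, edges)


def write_msi_tsv(graph: nx.Graph, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "source_id": u,
                "source_type": graph.nodes[u]["type"],
                "relation": "assoc",
                "target_id": v,
                "target_type": graph.nodes[v]["type"],
            }
            for u, v in sorted(tuple(sorted(e)) for e in graph.edges)
        ]
    ).to_csv(path, sep="\t", index=False)


def write_profile_tsv(
    profile: DiffusionProfile, graph: nx.Graph, path: str | Path
) -> None:
    rows = [
        {"node": n, "type": graph.nodes[n]["type"], "probability": p}
        for n, p in sorted(profile.visitation.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def subgraph_to_json(sub: MechanismSubgraph) -> dict:
    return {
        "drug": sub.drug,
        "disease": sub.disease,
        "allowed_nodes": sorted(sub.allowed_nodes),
        "paths": sub.paths,
        "nodes": sorted(sub.nodes),
        "edges": sorted(list(e) for e in sub.edges),
    }


def subgraph_to_dot(sub: MechanismSubgraph, graph: nx.Graph) -> str:
    shape = {
        "drug": "box",
        "disease": "diamond",
        "protein": "ellipse",
        "biological_function": "hexagon",
    }
    lines = ["graph mechanism {"]
    for n in sorted(sub.nodes):
        lines.append(
            f'  "{n}" [shape={shape[graph.nodes[n]["type"]]}];'
        )
    for a, b in sorted(sub.edges):
        lines.append(f'  "{a}" -- "{b}";')
    lines.append("}")
    return "\n".join(lines)
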