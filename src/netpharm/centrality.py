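"""Node centrality measures, median-consensus hub selection, MCC ranking.

Six measures are computed per node of an undirected simple graph:

* **DC** — degree centrality, the raw neighbour count ``|N(v)|``.
* **BC** — betweenness, the sum over unordered node pairs {s,t} (s,t != v)
  of the fraction of shortest s-t paths passing through v. Unnormalised;
  pairs in different components contribute 0.
* **CC** — closeness, normalised within v's connected component of size
  n_c: ``(n_c - 1) / sum of distances from v``; isolated nodes score 0.
* **EC** — eigenvector centrality, the principal eigenvector of the
  adjacency matrix (power iteration), non-negative with unit Euclidean
  norm over all nodes.
* **LAC** — local average connectivity: the mean degree of v's neighbours
  within the subgraph induced by the neighbourhood N(v).
* **NC** — network centrality: the sum over incident edges of the edge
  clustering coefficient ``ECC(u,w) = z / min(deg(u)-1, deg(w)-1)`` where
  z counts triangles on the edge; a degenerate denominator gives 0 (or 1,
  by flag).

Hub selection is *median-consensus*: a node is retained only if it meets
the per-metric median on all six measures simultaneously. Retained hubs
are then ranked by **MCC** (maximal clique centrality): the sum over
maximal cliques C containing v of ``(|C| - 1)!``, an exact integer that
strongly favours members of large dense subgraphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CliqueCapExceeded, ConvergenceError, DomainError

__all__ = [
    "METRICS",
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "eigenvector_centrality",
    "local_average_connectivity",
    "network_centrality",
    "compute_all",
    "median_filter",
    "HubSelection",
    "mcc",
    "MCCRanking",
    "top_k",
]

#: Column order of a centrality table (one row per node).
METRICS = ("dc", "bc", "cc", "ec", "lac", "nc")


def degree_centrality(g: nx.Graph) -> dict[str, int]:
    """Raw degree ``dc(v) = |N(v)|`` (integer, unnormalised)."""
    return {v: int(d) for v, d in g.degree()}


def betweenness_centrality(g: nx.Graph) -> dict[str, float]:
    """Unnormalised betweenness over unordered pairs (Brandes accumulation)."""
    return dict(nx.betweenness_centrality(g, normalized=False))


def closeness_centrality(g: nx.Graph) -> dict[str, float]:
    """Per-component closeness ``(n_c - 1) / sum of distances``; isolates 0."""
    return dict(nx.closeness_centrality(g, wf_improved=False))


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000
) -> dict[str, float]:
    """Principal adjacency eigenvector by power iteration.

    The iteration runs on ``A + I`` (same eigenvectors as ``A``; the shift
    makes the dominant eigenvalue strictly largest in modulus so bipartite
    graphs do not oscillate) from a uniform start, renormalising to unit
    Euclidean norm each step. Converged when the max absolute change of
    the normalised iterate drops below ``tol``.

    Raises
    ------
    DomainError
        If the graph has no edges (the measure is undefined).
    ConvergenceError
        If ``max_iter`` is exhausted — an explicit failure, never a
        silent partial result.
    """
    if g.number_of_edges() == 0:
        raise DomainError("eigenvector centrality requires at least one edge")
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
    np.fill_diagonal(a, a.diagonal() + 1.0)  # spectral shift
    x = np.full(len(nodes), 1.0 / math.sqrt(len(nodes)))
    for _ in range(max_iter):
        y = a @ x
        y /= np.linalg.norm(y)
        if np.max(np.abs(y - x)) < tol:
            y = np.clip(y, 0.0, None)
            y /= np.linalg.norm(y)
            return dict(zip(nodes, y.tolist()))
        x = y
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations (tol={tol})"
    )


def local_average_connectivity(g: nx.Graph) -> dict[str, float]:
    """Mean induced degree of the neighbourhood; 0 for degree-0 nodes."""
    out: dict[str, float] = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        out[v] = 2.0 * sub.number_of_edges() / len(nbrs)
    return out


def _ecc(g: nx.Graph, u: str, w: str, degenerate_value: float) -> float:
    denom = min(g.degree(u) - 1, g.degree(w) - 1)
    if denom <= 0:
        return degenerate_value
    z = len(set(g.neighbors(u)) & set(g.neighbors(w)))
    return z / denom


def network_centrality(
    g: nx.Graph, degenerate_value: float = 0.0
) -> dict[str, float]:
    """Sum of edge clustering coefficients over each node's incident edges.

    ``degenerate_value`` is the ECC assigned when an endpoint has degree 1
    (denominator 0); the default convention is 0.
    """
    out: dict[str, float] = {}
    for v in g.nodes:
        out[v] = sum(_ecc(g, v, w, degenerate_value) for w in g.neighbors(v))
    return out


def compute_all(
    g: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000
) -> pd.DataFrame:
    """All six measures as a DataFrame indexed by node, columns ``METRICS``.

    Eigenvector non-convergence propagates. An empty graph yields an
    empty table; a graph with nodes but no edges is rejected (eigenvector
    centrality is undefined there).
    """
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=list(METRICS))
    cols = {
        "dc": degree_centrality(g),
        "bc": betweenness_centrality(g),
        "cc": closeness_centrality(g),
        "ec": eigenvector_centrality(g, tol=tol, max_iter=max_iter),
        "lac": local_average_connectivity(g),
        "nc": network_centrality(g),
    }
    df = pd.DataFrame(cols, index=list(g.nodes))
    df.index.name = "gene"
    return df


@dataclass(frozen=True)
class HubSelection:
    """Result of the median-consensus filter.

    ``medians`` are the thresholds actually applied (computed from the
    table unless supplied); ``retained`` is ordered by degree descending,
    ties alphabetical.
    """

    medians: Mapping[str, float]
    retained: tuple[str, ...]
    rule: Literal["inclusive", "strict"]


def median_filter(
    table: pd.DataFrame,
    rule: Literal["inclusive", "strict"] = "inclusive",
    medians: Mapping[str, float] | None = None,
) -> HubSelection:
    """Retain nodes meeting the per-metric median on all six measures.

    The median of an even-length column is the mean of the two middle
    values. ``rule="inclusive"`` keeps values equal to the median (the
    default, since a node *at* every median is as central as half the
    network); ``rule="strict"`` requires strictly greater. Precomputed
    ``medians`` (e.g. published ones from a larger table) may be supplied
    in place of the table's own.
    """
    if table.empty:
        raise ValueError("median_filter requires a non-empty table")
    if rule not in ("inclusive", "strict"):
        raise ValueError(f"unknown rule {rule!r}")
    med = (
        dict(medians)
        if medians is not None
        else {m: float(table[m].median()) for m in METRICS}
    )
    if rule == "inclusive":
        mask = np.logical_and.reduce([table[m] >= med[m] for m in METRICS])
    else:
        mask = np.logical_and.reduce([table[m] > med[m] for m in METRICS])
    kept = table.loc[mask]
    order = sorted(kept.index, key=lambda v: (-kept.at[v, "dc"], str(v)))
    return HubSelection(medians=med, retained=tuple(order), rule=rule)


@dataclass(frozen=True)
class MCCRanking:
    """Exact MCC scores plus the degree used for tie-breaking.

    Ordering is by MCC descending, then degree descending, then node name
    ascending; the applied rule is recorded in ``tie_break``.
    """

    scores: Mapping[str, int]
    degrees: Mapping[str, int]
    tie_break: str = field(default="mcc desc, degree desc, name asc")

    def ordered(self) -> list[str]:
        return sorted(
            self.scores,
            key=lambda v: (-self.scores[v], -self.degrees[v], str(v)),
        )


def mcc(g: nx.Graph, max_cliques: int = 1_000_000) -> MCCRanking:
    """Maximal clique centrality via Bron-Kerbosch enumeration with pivoting.

    ``mcc(v)`` sums ``(|C| - 1)!`` over maximal cliques C containing v,
    in exact integer arithmetic. Isolated nodes score 0. Enumerating more
    than ``max_cliques`` maximal cliques raises
    :class:`CliqueCapExceeded` rather than running unbounded.
    """
    scores: dict[str, int] = {v: 0 for v in g.nodes}
    for i, clique in enumerate(nx.find_cliques(g)):
        if i >= max_cliques:
            raise CliqueCapExceeded(
                f"more than {max_cliques} maximal cliques; raise the cap "
                "to proceed"
            )
        if len(clique) < 2:  # singleton "clique" = isolated node, scores 0
            continue
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return MCCRanking(scores=scores, degrees=degree_centrality(g))


def top_k(ranking: MCCRanking, k: int) -> list[str]:
    """The ``k`` highest-MCC nodes under the ranking's recorded tie-break."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking.scores):
        raise ValueError(f"k={k} exceeds node count {len(ranking.scores)}")
    return ranking.ordered()[:k]
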