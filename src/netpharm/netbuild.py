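"""Construction of the compound-target bipartite network and PPI ingest.

The protein-protein interaction (PPI) graph is an undirected simple
``networkx.Graph`` over gene symbols. Edges carry an optional integer
``score`` attribute in [0, 1000] — the STRING-style combined confidence —
which is used only for ingest filtering; all downstream centrality work
treats the graph as unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .compounds import CompoundRecord
from .errors import ParseError
from .targets import GeneSet, TargetMap, normalize_symbol

__all__ = [
    "BipartiteNetwork",
    "build_bipartite",
    "read_ppi_edgelist",
    "write_ppi_edgelist",
    "remove_isolated_nodes",
    "degree_rank_report",
    "DEFAULT_SCORE_MIN",
]

# STRING's "medium confidence" cut; applied at ingest unless overridden.
DEFAULT_SCORE_MIN = 400


@dataclass(frozen=True)
class BipartiteNetwork:
    """Compound-target bipartite graph (no within-layer edges).

    Every edge endpoint is present in its node set; compounds with no
    retained edges are dropped at construction, mirroring how target-less
    compounds vanish from a published compound-target figure.
    """

    compound_nodes: frozenset[str]
    gene_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for cid, gene in self.edges:
            if cid not in self.compound_nodes or gene not in self.gene_nodes:
                raise ValueError(f"edge ({cid}, {gene}) has endpoint outside node sets")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.compound_nodes, bipartite="compound")
        g.add_nodes_from(self.gene_nodes, bipartite="gene")
        g.add_edges_from(self.edges)
        return g

    def write_sif(self, path: str | Path, interaction: str = "targets") -> None:
        """Write a SIF-like TSV (``source  interaction  target``)."""
        with Path(path).open("w", encoding="utf-8") as fh:
            for cid, gene in sorted(self.edges):
                fh.write(f"{cid}\t{interaction}\t{gene}\n")


def build_bipartite(
    target_map: TargetMap,
    compounds: Iterable[CompoundRecord],
    genes: GeneSet,
) -> BipartiteNetwork:
    """Restrict a target map to (given compounds) x (given genes).

    Edges are exactly the map pairs with both endpoints in the given sets;
    compounds left with zero edges are dropped, genes with zero edges are
    dropped too.
    """
    compound_ids = {c.compound_id for c in compounds}
    edges = {
        (cid, sym)
        for cid, sym in target_map.pairs
        if cid in compound_ids and sym in genes.genes
    }
    return BipartiteNetwork(
        compound_nodes=frozenset(cid for cid, _ in edges),
        gene_nodes=frozenset(sym for _, sym in edges),
        edges=frozenset(edges),
    )


def _check_handshake(g: nx.Graph) -> None:
    degs = sum(d for _, d in g.degree())
    assert degs == 2 * g.number_of_edges(), "handshake lemma violated"


def read_ppi_edgelist(
    path: str | Path, score_min: int = DEFAULT_SCORE_MIN
) -> nx.Graph:
    """Read a STRING-export-like edge list into an undirected simple graph.

    Expects whitespace- or tab-delimited columns
    ``protein1 protein2 combined_score`` (score optional; a header line
    naming them is skipped). Both orientations of a pair collapse to one
    edge, self-loops are dropped, and edges with ``score < score_min`` are
    discarded. Scoreless rows always pass the filter.
    """
    path = Path(path)
    g = nx.Graph()
    with path.open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if line_no == 1 and parts[0].lower() in {"protein1", "source", "node1"}:
                continue
            if len(parts) < 2:
                raise ParseError(
                    f"{path}: line {line_no}: expected at least two columns"
                )
            u, v = normalize_symbol(parts[0]), normalize_symbol(parts[1])
            score = None
            if len(parts) >= 3:
                try:
                    score = int(parts[2])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {line_no}: combined_score must be an "
                        f"integer, got {parts[2]!r}"
                    )
            if u == v:
                continue
            if score is not None and score < score_min:
                continue
            if score is None:
                g.add_edge(u, v)
            else:
                # keep the max score if both orientations appear
                prev = g.get_edge_data(u, v, default={}).get("score", -1)
                g.add_edge(u, v, score=max(score, prev))
    _check_handshake(g)
    return g


def write_ppi_edgelist(g: nx.Graph, path: str | Path) -> None:
    """Serialise a PPI graph back to the STRING-like three-column TSV."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v, data in sorted(g.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{b}\t{data.get('score', 1000)}\n")


def remove_isolated_nodes(g: nx.Graph, keep: GeneSet | None = None) -> nx.Graph:
    """Drop degree-0 nodes ("discrete points"), optionally after restriction.

    If ``keep`` is given the graph is first induced on those genes, so
    nodes isolated *within the restricted network* are removed. The edge
    set among remaining nodes is unchanged.
    """
    if keep is not None:
        g = g.subgraph(n for n in g.nodes if n in keep.genes)
    out = g.copy()
    out.remove_nodes_from([n for n, d in g.degree() if d == 0])
    return out


def degree_rank_report(g: nx.Graph) -> list[tuple[str, int]]:
    """Nodes sorted by degree descending, ties alphabetical."""
    return sorted(g.degree(), key=lambda item: (-item[1], item[0]))
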