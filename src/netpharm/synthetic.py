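"""Synthetic inputs with planted ground truth, plus packaged fixtures.

Real herb-pair studies pull their inputs from databases (compound tables
with ADME descriptors, compound-target lookups, disease gene lists,
STRING interaction exports, GO/KEGG annotation sets). Those pulls are
neither versioned nor redistributable, so this module generates
statistically similar stand-ins with *known* ground truth:

* compound tables with controllable OB/DL pass rates,
* bipartite target maps with planted herb-herb and drug-disease overlaps,
* scale-free (preferential-attachment) PPI graphs with a planted clique,
* annotation collections with one planted enriched term.

Every generator is a pure function of :class:`SimConfig` — the same seed
reproduces the same data bit for bit — and returns a *manifest* recording
every quantity the pipeline should later recover, enabling closed-loop
tests of every stage.

Two fixture tables transcribed from a published herb-pair COPD study ship
with the package: ``table1`` (39 candidate compounds of Fuzi and Banxia
with OB/DL descriptors) and ``table2`` (the 13 hub genes surviving the
median-consensus filter, with their six centrality values and the
published per-metric medians as metadata).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .compounds import CompoundRecord, DEFAULT_DL_MIN, DEFAULT_OB_MIN, adme_filter
from .enrichment import AnnotationCollection
from .netbuild import write_ppi_edgelist
from .targets import GeneSet, TargetMap

__all__ = [
    "SimConfig",
    "gen_compound_table",
    "gen_target_map",
    "gen_disease_genes",
    "gen_ppi",
    "gen_annotations",
    "simulate_bundle",
    "load_fixture",
]

# stream constants so each generator draws from an independent substream
_STREAM_COMPOUNDS = 0
_STREAM_TARGETS = 1
_STREAM_DISEASE = 2
_STREAM_PPI = 3
_STREAM_ANNOTATIONS = 4


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic data generators.

    Defaults mirror the scale of a typical two-herb study: 26 + 13
    candidate compounds, per-herb target sets of 13 and 41 genes sharing
    7, a disease list of 7,153 genes planted to hit 44 drug targets, a
    39-node preferential-attachment PPI with a planted 6-clique, and 50
    annotation terms with one planted enriched term.
    """

    seed: int = 0
    herbs: tuple[str, ...] = ("HerbA", "HerbB")
    n_compounds: tuple[int, ...] = (26, 13)
    ob_range: tuple[float, float] = (0.0, 100.0)
    dl_range: tuple[float, float] = (0.0, 1.0)
    ob_min: float = DEFAULT_OB_MIN
    dl_min: float = DEFAULT_DL_MIN
    targets_per_compound: float = 3.0
    mapped_per_herb: tuple[int, ...] = (6, 10)
    herb_target_sizes: tuple[int, ...] = (13, 41)
    herb_overlap: int = 7
    gene_universe_size: int = 20_000
    disease_gene_count: int = 7_153
    planted_overlap: int = 44
    ppi_nodes: int = 39
    ppi_attachment: int = 5
    planted_clique_size: int = 6
    score_range: tuple[int, int] = (400, 999)
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 60)
    planted_term_hits: int = 10

    def __post_init__(self) -> None:
        if len(self.n_compounds) != len(self.herbs):
            raise ValueError("n_compounds must match herbs")
        if self.herb_overlap > min(self.herb_target_sizes):
            raise ValueError("herb_overlap exceeds a herb target-set size")
        drug_union = sum(self.herb_target_sizes) - self.herb_overlap
        if self.planted_overlap > min(drug_union, self.disease_gene_count):
            raise ValueError(
                "planted_overlap exceeds drug target union or disease list size"
            )
        if self.planted_clique_size > self.ppi_nodes:
            raise ValueError("planted_clique_size exceeds ppi_nodes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def universe(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.gene_universe_size + 1)]


def gen_compound_table(
    cfg: SimConfig,
) -> tuple[list[CompoundRecord], dict]:
    """Compound table with OB/DL drawn uniformly from the configured ranges.

    The manifest records the expected ADME pass/fail of every record and
    per-herb pass counts.
    """
    rng = cfg.rng(_STREAM_COMPOUNDS)
    records: list[CompoundRecord] = []
    idx = 0
    for herb, n in zip(cfg.herbs, cfg.n_compounds):
        for _ in range(n):
            idx += 1
            records.append(
                CompoundRecord(
                    compound_id=f"C{idx:04d}",
                    name=f"compound-{idx}",
                    ob=float(rng.uniform(*cfg.ob_range)),
                    dl=float(rng.uniform(*cfg.dl_range)),
                    herb=herb,
                )
            )
    passing = adme_filter(records, cfg.ob_min, cfg.dl_min)
    pass_ids = {r.compound_id for r in passing}
    manifest = {
        "pass": {r.compound_id: r.compound_id in pass_ids for r in records},
        "n_records": len(records),
        "n_pass": len(passing),
        "n_pass_per_herb": {
            herb: sum(1 for r in passing if r.herb == herb) for herb in cfg.herbs
        },
    }
    return records, manifest


def gen_target_map(
    cfg: SimConfig, compounds: Sequence[CompoundRecord]
) -> tuple[TargetMap, dict]:
    """Bipartite compound-target map with planted per-herb target sets.

    For each herb a pool of ``herb_target_sizes`` genes is drawn from the
    universe, the first two herbs sharing exactly ``herb_overlap`` genes.
    ``mapped_per_herb`` compounds per herb (never ``manual_add`` ones,
    which contribute no targets) receive the pool genes round-robin so
    the realised per-herb target set equals the pool exactly, then each
    mapped compound draws Poisson(``targets_per_compound``) extra genes
    from its herb pool. The manifest records the true per-herb sets,
    their overlap and union, and which compounds are mapped.
    """
    rng = cfg.rng(_STREAM_TARGETS)
    universe = cfg.universe()
    shared = [str(g) for g in rng.choice(universe, size=cfg.herb_overlap, replace=False)]
    remaining = [g for g in universe if g not in set(shared)]
    pools: dict[str, list[str]] = {}
    offset = 0
    for i, herb in enumerate(cfg.herbs):
        n_unique = cfg.herb_target_sizes[i] - (cfg.herb_overlap if i < 2 else 0)
        unique = remaining[offset : offset + n_unique]
        offset += n_unique
        pools[herb] = (shared if i < 2 else []) + unique

    pairs: set[tuple[str, str]] = set()
    mapped_ids: dict[str, list[str]] = {}
    for i, herb in enumerate(cfg.herbs):
        eligible = [
            c.compound_id
            for c in compounds
            if c.herb == herb and not c.manual_add
        ]
        n_mapped = min(cfg.mapped_per_herb[i], len(eligible))
        chosen = (
            [str(c) for c in rng.choice(eligible, size=n_mapped, replace=False)]
            if n_mapped
            else []
        )
        mapped_ids[herb] = sorted(chosen)
        if not chosen:
            continue
        pool = pools[herb]
        for j, gene in enumerate(pool):  # cover the pool exactly
            pairs.add((chosen[j % len(chosen)], gene))
        for cid in chosen:
            extra = rng.poisson(cfg.targets_per_compound)
            if extra:
                for gene in rng.choice(pool, size=min(extra, len(pool)), replace=False):
                    pairs.add((cid, str(gene)))

    tmap = TargetMap(frozenset(pairs))
    herb_sets = {
        herb: sorted(
            {g for cid, g in pairs if cid in set(mapped_ids[herb])}
        )
        for herb in cfg.herbs
    }
    union = sorted(set().union(*herb_sets.values())) if herb_sets else []
    overlap = (
        sorted(set(herb_sets[cfg.herbs[0]]) & set(herb_sets[cfg.herbs[1]]))
        if len(cfg.herbs) >= 2
        else []
    )
    manifest = {
        "herb_targets": herb_sets,
        "herb_overlap": overlap,
        "drug_union": union,
        "mapped_compounds": mapped_ids,
        "n_mapped": sum(len(v) for v in mapped_ids.values()),
        "n_unmapped": len(compounds) - sum(len(v) for v in mapped_ids.values()),
        "n_pairs": len(pairs),
    }
    return tmap, manifest


def gen_disease_genes(cfg: SimConfig, drug: GeneSet) -> tuple[GeneSet, dict]:
    """Disease gene list planted to share ``planted_overlap`` genes with
    the drug target set; remaining genes drawn from the rest of the
    universe."""
    rng = cfg.rng(_STREAM_DISEASE)
    drug_genes = sorted(drug.genes)
    if cfg.planted_overlap > len(drug_genes):
        raise ValueError("planted_overlap exceeds drug target count")
    hit = [str(g) for g in rng.choice(drug_genes, size=cfg.planted_overlap, replace=False)]
    background = [g for g in cfg.universe() if g not in drug.genes]
    n_rest = cfg.disease_gene_count - cfg.planted_overlap
    rest = [str(g) for g in rng.choice(background, size=n_rest, replace=False)]
    genes = GeneSet.from_iterable("disease", hit + rest)
    manifest = {
        "n_disease": len(genes),
        "planted_overlap": sorted(hit),
        "n_overlap": len(hit),
    }
    return genes, manifest


def gen_ppi(
    cfg: SimConfig, genes: Sequence[str] | None = None
) -> tuple[nx.Graph, dict]:
    """Scale-free PPI with an optionally planted clique.

    A Barabási-Albert preferential-attachment graph on ``ppi_nodes``
    nodes (attachment parameter ``ppi_attachment``; 1 gives a tree) forms
    the heavy-tailed backbone; ``planted_clique_size`` nodes are then
    fully interconnected. Node names come from ``genes`` when supplied
    (a random subset of size ``ppi_nodes``), else ``P001``-style labels.
    Edges carry integer confidence scores drawn from ``score_range``.
    """
    rng = cfg.rng(_STREAM_PPI)
    n = cfg.ppi_nodes
    m = min(cfg.ppi_attachment, n - 1)
    g = nx.barabasi_albert_graph(n, m, seed=rng)
    if genes is not None:
        if len(genes) < n:
            raise ValueError(f"need at least {n} gene names, got {len(genes)}")
        names = [str(g) for g in rng.choice(sorted(genes), size=n, replace=False)]
    else:
        names = [f"P{i:03d}" for i in range(1, n + 1)]
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    clique: list[str] = []
    if cfg.planted_clique_size >= 2:
        clique = sorted(
            str(g) for g in rng.choice(names, size=cfg.planted_clique_size, replace=False)
        )
        for i, u in enumerate(clique):
            for v in clique[i + 1 :]:
                g.add_edge(u, v)
    lo, hi = cfg.score_range
    for u, v in g.edges:
        g.edges[u, v]["score"] = int(rng.integers(lo, hi + 1))
    manifest = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "clique": clique,
    }
    return g, manifest


def gen_annotations(
    cfg: SimConfig, query: GeneSet
) -> tuple[AnnotationCollection, dict]:
    """Annotation collection with one planted enriched term.

    The universe is the configured gene universe extended with the query
    genes. Background terms draw their members uniformly from the
    universe; the planted term receives ``planted_term_hits`` query genes
    plus non-query filler up to its size.
    """
    rng = cfg.rng(_STREAM_ANNOTATIONS)
    universe = sorted(set(cfg.universe()) | set(query.genes))
    non_query = [g for g in universe if g not in query.genes]
    lo, hi = cfg.term_size_range
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    hits = min(cfg.planted_term_hits, len(query.genes))
    size = max(int(rng.integers(lo, hi + 1)), hits)
    planted_genes = {str(g) for g in rng.choice(sorted(query.genes), size=hits, replace=False)}
    planted_genes |= {str(g) for g in rng.choice(non_query, size=size - hits, replace=False)}
    planted_id = "T0000"
    terms[planted_id] = ("planted enriched term", frozenset(planted_genes))
    for i in range(1, cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        terms[f"T{i:04d}"] = (f"background term {i}", members)
    collection = AnnotationCollection(terms=terms, universe=frozenset(universe))
    manifest = {
        "planted_term": planted_id,
        "planted_hits": hits,
        "planted_size": len(terms[planted_id][1]),
        "n_terms": len(terms),
    }
    return collection, manifest


def _write_gmt(collection: AnnotationCollection, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for term_id, (desc, genes) in collection.terms.items():
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")


def simulate_bundle(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate and write all five pipeline inputs plus ``manifest.json``.

    Files written: ``compounds.tsv``, ``targets.tsv``,
    ``disease_genes.txt``, ``ppi.tsv``, ``annotations.gmt``. The returned
    (and serialised) manifest aggregates every generator's ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds, m_comp = gen_compound_table(cfg)
    with (outdir / "compounds.tsv").open("w", encoding="utf-8") as fh:
        fh.write("id\tname\tob\tdl\tsource\tmanual_add\n")
        for r in compounds:
            fh.write(
                f"{r.compound_id}\t{r.name}\t{r.ob:.4f}\t{r.dl:.4f}"
                f"\t{r.herb}\t{str(r.manual_add).lower()}\n"
            )
    tmap, m_map = gen_target_map(cfg, compounds)
    with (outdir / "targets.tsv").open("w", encoding="utf-8") as fh:
        for cid, gene in sorted(tmap.pairs):
            fh.write(f"{cid}\t{gene}\n")
    drug = GeneSet("drug", frozenset(m_map["drug_union"]))
    disease, m_dis = gen_disease_genes(cfg, drug)
    with (outdir / "disease_genes.txt").open("w", encoding="utf-8") as fh:
        fh.writelines(f"{g}\n" for g in sorted(disease.genes))
    overlap = sorted(set(m_dis["planted_overlap"]))
    ppi_pool = overlap if len(overlap) >= cfg.ppi_nodes else None
    ppi, m_ppi = gen_ppi(cfg, genes=ppi_pool)
    write_ppi_edgelist(ppi, outdir / "ppi.tsv")
    # plant the enriched term on the consensus hubs this PPI will yield,
    # so the enrichment stage closes the loop end to end
    from .centrality import compute_all, median_filter

    hubs = median_filter(compute_all(ppi)).retained
    m_ppi = {**m_ppi, "median_hubs": list(hubs)}
    ann, m_ann = gen_annotations(cfg, GeneSet("hubs", frozenset(hubs)))
    _write_gmt(ann, outdir / "annotations.gmt")
    manifest = {
        "config": asdict(cfg),
        "compounds": m_comp,
        "target_map": m_map,
        "disease": m_dis,
        "ppi": m_ppi,
        "annotations": m_ann,
    }
    with (outdir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str) -> Path:
    return Path(str(resources.files("netpharm") / "data" / name))


def load_fixture(name: str):
    """Load a packaged fixture table.

    ``"table1"`` returns the 39-row compound table as a list of
    :class:`~netpharm.compounds.CompoundRecord`. ``"table2"`` returns a
    DataFrame of the 13 consensus hub genes with columns
    ``dc, ec, lac, bc, cc, nc`` indexed by gene symbol; the published
    per-metric medians of the full network are in ``df.attrs["medians"]``.
    """
    if name == "table1":
        from .compounds import read_compound_table

        return read_compound_table(_data_path("table1.tsv"))
    if name == "table2":
        path = _data_path("table2.tsv")
        medians: dict[str, float] = {}
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("# median"):
                    for token in line.split("\t")[1:]:
                        key, val = token.strip().split("=")
                        medians[key] = float(val)
        df = pd.read_csv(path, sep="\t", comment="#", index_col="gene")
        df.attrs["medians"] = medians
        return df
    raise ValueError(f"unknown fixture {name!r}; expected 'table1' or 'table2'")
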