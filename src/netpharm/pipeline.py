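"""End-to-end pipeline: screen -> targets -> overlap -> networks -> hubs -> ORA.

Mirrors the standard herb-pair network-pharmacology flow: ADME-screen the
compound tables, map compounds to targets, intersect herb target sets
with each other and with the disease gene list, build the compound-target
bipartite network, clean the PPI graph, select consensus hubs by the
six-metric median filter, rank them by MCC, and test the hubs for
annotation-term over-representation.

Each stage writes a TSV artefact into the output directory, and
``run_pipeline`` emits a versioned JSON run report carrying every count
an analyst would quote (compounds passing, per-herb target sizes, overlap
sizes, network node/edge counts, medians, hubs, top-k, significant
terms) plus every threshold used.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from . import centrality as ctr
from . import compounds as cmp
from . import enrichment as enr
from . import netbuild as nb
from . import targets as tg
from .errors import NetpharmError, StageError

__all__ = ["PipelineConfig", "run_pipeline", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

log = logging.getLogger("netpharm")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run. All thresholds are logged."""

    compounds: Path
    targets: Path
    disease_genes: Path
    ppi: Path
    annotations: Path
    outdir: Path
    ob_min: float = cmp.DEFAULT_OB_MIN
    dl_min: float = cmp.DEFAULT_DL_MIN
    include_manual: bool = False
    score_min: int = nb.DEFAULT_SCORE_MIN
    median_rule: Literal["inclusive", "strict"] = "inclusive"
    top_k: int = 5
    p_cut: float = 0.05
    q_cut: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("compounds", "targets", "disease_genes", "ppi", "annotations", "outdir"):
            setattr(self, name, Path(getattr(self, name)))


def _stage(name: str):
    """Decorator: log stage timing and wrap failures in StageError."""

    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - mapped to exit code 3
                raise StageError(name, str(exc)) from exc
            log.info("stage %s: done in %.3fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("screen")
def _screen(cfg: PipelineConfig, report: dict) -> list[cmp.CompoundRecord]:
    records = cmp.read_compound_table(cfg.compounds)
    active = cmp.adme_filter(
        records, cfg.ob_min, cfg.dl_min, include_manual=cfg.include_manual
    )
    active_ids = {(r.herb, r.compound_id) for r in active}
    with (cfg.outdir / "screened.tsv").open("w", encoding="utf-8") as fh:
        fh.write("id\tname\tob\tdl\tsource\tmanual_add\tpassed\n")
        for r in records:
            fh.write(
                f"{r.compound_id}\t{r.name}\t{r.ob}\t{r.dl}\t{r.herb}\t"
                f"{str(r.manual_add).lower()}\t"
                f"{str((r.herb, r.compound_id) in active_ids).lower()}\n"
            )
    herbs = sorted({r.herb for r in records})
    report["screen"] = {
        "n_input": len(records),
        "n_active": len(active),
        "n_active_per_herb": {
            h: sum(1 for r in active if r.herb == h) for h in herbs
        },
        "max_ob_per_herb": {
            h: {"compound": s.best.name, "ob": s.max_ob}
            for h, s in cmp.per_herb_summary(records).items()
        },
    }
    return active


@_stage("targets")
def _targets(
    cfg: PipelineConfig, report: dict, active: list[cmp.CompoundRecord]
) -> tuple[tg.TargetMap, tg.GeneSet]:
    tmap = tg.read_target_map(cfg.targets)
    herbs = sorted({r.herb for r in active})
    herb_sets = {
        h: tg.targets_of_herb(tmap, [r for r in active if r.herb == h], label=h)
        for h in herbs
    }
    for h, gs in herb_sets.items():
        with (cfg.outdir / f"targets_{h}.txt").open("w", encoding="utf-8") as fh:
            fh.writelines(f"{g}\n" for g in sorted(gs.genes))
    drug = tg.GeneSet(
        "drug", frozenset().union(*(gs.genes for gs in herb_sets.values()))
    )
    entry: dict = {
        "per_herb": {h: len(gs) for h, gs in herb_sets.items()},
        "n_drug_targets": len(drug),
        "n_mapped_compounds": sum(
            1 for r in active if tmap.targets_of(r.compound_id)
        ),
        "n_unmapped_compounds": sum(
            1 for r in active if not tmap.targets_of(r.compound_id)
        ),
    }
    if len(herbs) >= 2:
        rep = tg.set_intersection_report(herb_sets[herbs[0]], herb_sets[herbs[1]])
        entry["herb_venn"] = {
            "a": rep.label_a,
            "b": rep.label_b,
            "size_a": rep.size_a,
            "size_b": rep.size_b,
            "intersection": rep.n_intersection,
            "union": rep.n_union,
            "common_genes": list(rep.intersection),
        }
    report["targets"] = entry
    return tmap, drug


@_stage("overlap")
def _overlap(cfg: PipelineConfig, report: dict, drug: tg.GeneSet) -> tg.GeneSet:
    disease = tg.read_gene_list(cfg.disease_genes, label="disease")
    overlap = tg.drug_disease_overlap(drug, disease)
    with (cfg.outdir / "overlap.txt").open("w", encoding="utf-8") as fh:
        fh.writelines(f"{g}\n" for g in sorted(overlap.genes))
    report["overlap"] = {
        "n_disease": len(disease),
        "n_drug": len(drug),
        "n_overlap": len(overlap),
    }
    return overlap


@_stage("network")
def _network(
    cfg: PipelineConfig,
    report: dict,
    tmap: tg.TargetMap,
    active: list[cmp.CompoundRecord],
    overlap: tg.GeneSet,
) -> None:
    net = nb.build_bipartite(tmap, active, overlap)
    net.write_sif(cfg.outdir / "bipartite.sif")
    report["network"] = {
        "n_compounds": len(net.compound_nodes),
        "n_genes": len(net.gene_nodes),
        "n_edges": net.n_edges,
    }


@_stage("ppi")
def _ppi(cfg: PipelineConfig, report: dict, overlap: tg.GeneSet):
    g = nb.read_ppi_edgelist(cfg.ppi, score_min=cfg.score_min)
    clean = nb.remove_isolated_nodes(g, keep=overlap)
    nb.write_ppi_edgelist(clean, cfg.outdir / "ppi_clean.tsv")
    ranks = nb.degree_rank_report(clean)
    with (cfg.outdir / "ppi_degree_rank.tsv").open("w", encoding="utf-8") as fh:
        fh.write("gene\tdegree\n")
        fh.writelines(f"{g_}\t{d}\n" for g_, d in ranks)
    report["ppi"] = {
        "n_nodes_raw": g.number_of_nodes(),
        "n_edges_raw": g.number_of_edges(),
        "n_nodes": clean.number_of_nodes(),
        "n_edges": clean.number_of_edges(),
        "n_isolates_removed": len(overlap) - clean.number_of_nodes(),
    }
    return clean


@_stage("hubs")
def _hubs(cfg: PipelineConfig, report: dict, ppi) -> list[str]:
    table = ctr.compute_all(ppi)
    table.round(6).to_csv(cfg.outdir / "centrality.tsv", sep="\t")
    selection = ctr.median_filter(table, rule=cfg.median_rule)
    ranking = ctr.mcc(ppi)
    hub_ranking = ctr.MCCRanking(
        scores={v: ranking.scores[v] for v in selection.retained},
        degrees={v: ranking.degrees[v] for v in selection.retained},
    )
    k = min(cfg.top_k, len(selection.retained))
    top = ctr.top_k(hub_ranking, k) if k else []
    with (cfg.outdir / "hubs.txt").open("w", encoding="utf-8") as fh:
        fh.writelines(f"{g}\n" for g in selection.retained)
    report["hubs"] = {
        "medians": {m: selection.medians[m] for m in ctr.METRICS},
        "rule": selection.rule,
        "n_retained": len(selection.retained),
        "retained": list(selection.retained),
        "mcc": {v: hub_ranking.scores[v] for v in selection.retained},
        "top_k": top,
    }
    return list(selection.retained)


@_stage("enrich")
def _enrich(cfg: PipelineConfig, report: dict, hubs: list[str]) -> None:
    collection = enr.read_gmt(cfg.annotations)
    query = tg.GeneSet.from_iterable("hubs", hubs)
    result = enr.ora(query, collection, p_cut=cfg.p_cut, q_cut=cfg.q_cut)
    result.to_csv(cfg.outdir / "enrichment.tsv", sep="\t", index=False)
    sig = result[result["significant"]]
    report["enrichment"] = {
        "n_terms_tested": int(len(result)),
        "n_significant": int(len(sig)),
        "significant_terms": sig["term_id"].tolist(),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write ``report.json``; returns the report dict.

    Any stage failure raises :class:`StageError` naming the stage; the
    partially written report is flagged and saved for post-mortem.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "thresholds": {
            "ob_min": cfg.ob_min,
            "dl_min": cfg.dl_min,
            "include_manual": cfg.include_manual,
            "score_min": cfg.score_min,
            "median_rule": cfg.median_rule,
            "top_k": cfg.top_k,
            "p_cut": cfg.p_cut,
            "q_cut": cfg.q_cut,
            "seed": cfg.seed,
        },
    }
    try:
        active = _screen(cfg, report)
        tmap, drug = _targets(cfg, report, active)
        overlap = _overlap(cfg, report, drug)
        _network(cfg, report, tmap, active, overlap)
        ppi = _ppi(cfg, report, overlap)
        hubs = _hubs(cfg, report, ppi)
        _enrich(cfg, report, hubs)
    except NetpharmError:
        report["partial"] = True
        _write_report(cfg, report)
        raise
    report["partial"] = False
    _write_report(cfg, report)
    return report


def _write_report(cfg: PipelineConfig, report: dict) -> None:
    with (cfg.outdir / "report.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
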