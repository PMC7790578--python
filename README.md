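# netpharm

A tested, reusable implementation of the network-pharmacology inference
chain used to nominate hub targets and pathways for a two-herb
traditional-medicine pair (here: Fuzi, *Aconiti Lateralis Radix
Praeparata*, and Banxia, *Pinelliae Rhizoma*) against a disease (chronic
obstructive pulmonary disease). The chain is:

1. **ADME screening** — keep compounds with oral bioavailability
   OB ≥ 30 % and drug-likeness DL ≥ 0.18 (both inclusive);
2. **target mapping and set algebra** — per-herb target gene sets, the
   herb–herb Venn intersection, and the drug∩disease overlap;
3. **network construction** — the compound–target bipartite network and
   a STRING-style protein–protein interaction (PPI) graph, cleaned of
   isolated nodes;
4. **hub selection** — six node-centrality measures (DC, BC, CC, EC,
   LAC, NC) with *median-consensus* filtering: a gene is a hub only if it
   meets the per-metric median on all six measures simultaneously;
5. **hub ranking** — maximal clique centrality,
   `MCC(v) = Σ_{C ∋ v} (|C|−1)!` over maximal cliques `C`, exact integer
   arithmetic via Bron–Kerbosch enumeration;
6. **over-representation analysis** — hypergeometric upper-tail
   `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` per annotation term, with
   Benjamini–Hochberg q-values and p/q cutoffs of 0.05.

Because the database pulls behind such studies (TCMSP, DrugBank,
GeneCards/OMIM, STRING, GO/KEGG) are unversioned, every input can instead
be *generated* by the `synthetic` module with planted ground truth
(controllable ADME pass rates, planted herb/disease overlaps, scale-free
PPI backbones with a planted clique, one planted enriched term), so every
stage is testable end to end offline. Two transcribed fixture tables ship
with the package: the 39-compound two-herb table and the 13-gene hub
centrality table with its published per-metric medians.

Intended users: computational biologists who want a scriptable,
inspectable version of the Cytoscape/CytoNCA/CytoHubba + R workflow with
explicit conventions and exact statistics.

## Worked example

Generate a synthetic study (26 + 13 compounds, per-herb target sets of
13 and 41 genes sharing 7, a 7,153-gene disease list planted to hit 44
drug targets, a 39-node PPI) and run the full pipeline:

```sh
netpharm simulate --seed 42 --out demo/inputs
netpharm run-all \
  --compounds demo/inputs/compounds.tsv \
  --targets demo/inputs/targets.tsv \
  --disease-genes demo/inputs/disease_genes.txt \
  --ppi demo/inputs/ppi.tsv \
  --annotations demo/inputs/annotations.gmt \
  --out demo/out --ob-min 0 --dl-min 0
```

which prints

```json
{"report": "demo/out/report.json", "n_active": 39, "n_overlap": 44,
 "hubs": ["G00024", "G00011", "G08987", "G00006", "..."],
 "top_k": ["G00024", "G00004", "G00021", "G00006", "G00022"],
 "n_significant": 1}
```

`n_overlap: 44` is the planted drug∩disease overlap recovered by the
overlap stage; `top_k` are the five highest-MCC consensus hubs; the one
significant term is the planted enriched term. `demo/out/report.json`
carries every stage count (per-herb target sizes 13/41, herb Venn
intersection 7, 16 compounds with edges in the bipartite network, 39 PPI
nodes after removing 5 isolates, the six medians, per-hub MCC scores).

Screening the packaged compound table reproduces the published counts:

```sh
netpharm screen --compounds src/netpharm/data/table1.tsv --out screened.tsv
# {"n_active": 34, "per_herb": {"Banxia": 13, "Fuzi": 21}}
```

The same operations are available as a library:

```python
from netpharm import load_fixture, adme_filter, median_filter

table1 = load_fixture("table1")
print(len(adme_filter(table1, 30, 0.18)))     # 34
table2 = load_fixture("table2")
sel = median_filter(table2, medians=table2.attrs["medians"])
print(len(sel.retained), sel.retained[0])     # 13 FOS
```

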