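# convergene

Comparative-genomics toolkit for a recurring question in microbial
evolution: **do genomes isolated from similar environments share more gene
content than their phylogeny explains?**  Isolation-source classes
(aquatic, terrestrial, host-associated, ...) are often polyphyletic, yet
hierarchical clustering of gene *content* can still group organisms by
environment — a signature of convergent (lateral) gene acquisition, i.e.
homoplasy at the gene-content level.

The package implements the full inference chain as a tested library plus a
thin CLI:

1. **Orthology** — reciprocal best hits (RBH) from 13-column BLAST-tabular
   hit tables, filtered to alignments covering ≥ 70% of the query; reference-
   anchored ortholog groups with per-family occupancy (core = occupancy 1.0,
   Core-70 = present in ≥ 70% of genomes, i.e. ≥ ⌈0.7·n⌉ members).
2. **Genomic similarity** — the genomic similarity score
   `GSS(A,B) = Σ[S(a→b)+S(b→a)] / Σ[S(a→a)+S(b→b)]` over RBH pairs
   (∈ [0,1]); `1 − GSS` feeds Saitou–Nei neighbor joining with
   Phylip-style negative-branch clamping.
3. **Functional profiles** — per-genome sets of function identifiers
   (COG/Figfam-like) after PSSM-coverage (≥ 70%) and within-protein overlap
   (≤ 10%) filtering; Jaccard distances `Jd(A,B) = 1 − |A∩B|/|A∪B|`.
4. **Clustering** — Ward.D2 / average / complete / single linkage with the
   agglomerative coefficient `AC = 1 − mean(first-merge h / final h)`,
   silhouette widths, nested dendrogram cuts and the adjusted Rand index.
5. **Association** — one-sided hypergeometric cluster–environment
   enrichment scanned over cuts k = 3, 4, ... with Benjamini–Hochberg FDR
   per cut (the scan stops when significance is lost), and adaptive-function
   detection (exact one-sided 2×2 presence test, BH-corrected, reported at
   q ≤ 0.05 with ≥ 80% presence in the focal group).
6. **Tree congruence** — Robinson–Foulds symmetric differences on
   non-trivial unrooted bipartitions, and counts of nodes with support ≥ 80.
7. **Simulation** — a seeded generator (Yule phylogeny; clade-wise
   environment labels with controlled polyphyly; infinitely-many-genes
   gain/loss; disjoint per-environment pools of convergently acquired
   families; hit tables with distance-decaying bitscores) so every stage is
   testable against planted ground truth without any downloads.

## Worked example

Run the whole chain on a simulated dataset from the shell:

```bash
convergene run --seed 1 --out out/
```

which prints (exact output of the command above):

```
core=141 core70=164 best_linkage=ward AC=0.9426 significant=105 adaptive=121
```

Reading these numbers: 141 ortholog families occur in all 60 simulated
genomes and 164 in at least 70% of them; Ward linkage gives the clearest
content dendrogram (agglomerative coefficient 0.94); the cluster–environment
scan finds significant enrichment (105 significant rows across the scanned
cuts — every environment is recovered at the k = 3 cut), and 121 functions
pass the adaptive-function gates, the bulk of them the planted
environment-pool families.  All stage outputs (GSS matrix, NJ tree in
Newick, Jaccard matrix, merge table, partitions, silhouettes, association
and adaptive tables, RF matrix, `summary.md`, `run_log.txt`) are written to
`out/`.

The same analysis from Python:

```python
from convergene import (SimulationConfig, PipelineConfig, run_pipeline)

report = run_pipeline(PipelineConfig(simulate=SimulationConfig(seed=1)))
print(report.n_core, report.best_method, report.ari_environment)
```

Individual stages are plain functions (`find_rbh`, `compute_gss`,
`neighbor_joining`, `filter_assignments`, `profile_distance_matrix`,
`hierarchical_cluster`, `scan_cluster_environment_associations`,
`find_adaptive_functions`, `robinson_foulds`, ...) operating on pandas
DataFrames and dendropy trees, so any step can be run on user data — e.g.
a real BLAST hit table plus a genome → environment TSV.

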