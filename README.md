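# mirframe

Differential miRNA network analysis for two-condition transcriptome
comparisons (for example healthy versus virus-infected plant tissue).
`mirframe` is aimed at computational biologists who have assembled,
annotated transcriptomes plus expression estimates for two conditions
and want to go from "which miRNAs are active here?" to an interpretable
set of regulatory networks without stitching together half a dozen web
services.

The pipeline runs six stages:

1. **miRNA identification** — candidate mature-miRNA sites are found by
   scanning transcripts (both strands) against a mature reference with a
   mismatch budget and an occurrence e-value cutoff (default 1e-5). Each
   site's precursor window is folded with a built-in nearest-neighbor
   secondary-structure model (pluggable: any ViennaRNA-style command can
   replace it) and judged against six hairpin criteria: the window is a
   candidate precursor; it folds into a stem-loop; the mature lies in one
   arm; fewer than 7 mature positions fail to pair with the opposite arm;
   no terminal-loop overlap or unpaired run ≥ 3 splits the mature block;
   and the minimum free energy is ≤ −20 kcal/mol.
2. **Target prediction** — miRNAs are aligned antiparallel against every
   transcript window with penalties match 0, G:U wobble 0.5, mismatch
   1.0, gap 2.0, doubled over miRNA positions 2–13; only the first 20
   positions are scored. Sites with expectation ≤ 3 are kept (top 200
   per miRNA), and a mismatch at positions 9–11 calls translational
   inhibition instead of cleavage.
3. **Bipartite networks** — the interaction matrix A (A_ij = 1 iff
   miRNA i targets transcript j) becomes a directed miRNA→target
   bipartite graph; condition-unique and common-miRNA variants are built
   for differential comparison.
4. **GO node-score network** — every GO term g gets
   score(g) = Σ_{g_a ∈ desc(g)} gp(g_a) · α^dist(g, g_a)
   over its descendant closure (α = 0.6 by default); transcripts are
   scored through their annotations and clustered by equal score, with
   shared-term edges between clusters.
5. **Degree and correlation profiling** — node degrees, the degree
   distribution p(k), the endpoint-degree (assortativity) correlation
   r = [⟨jk⟩ − ⟨(j+k)/2⟩²] / [⟨(j²+k²)/2⟩ − ⟨(j+k)/2⟩²]
   over symmetrized edge endpoint degrees, and per-transcript Pearson
   correlations of replicate FPKM between conditions.
6. **Co-expression reconstruction** — candidate partners of each query
   gene are scored on rank-normalized abundance, GO Jaccard overlap and
   rescaled expression PCC, combined with weights 0.4/0.3/0.3, and the
   top 20 become its neighborhood in the undirected network.

The package also ships transcriptions of the published healthy (JH) /
virus-infected (JV) *Jatropha curcas* miRNA-target tables as fixtures,
and a synthetic-data module that plants criterion-profiled precursor
hairpins, perfect target sites, GO DAGs and correlated FPKM tables with
machine-readable truth tables.

## Worked example

`examples/` holds one short script per capability. Discovery on a
synthetic transcriptome with one compliant and one weak-stem plant
(`python examples/01_discover_mirnas.py`):

```
4 precursor candidates:
  miR-201  on tx001 236-256 (+) MFE  -46.3 kcal/mol -> accepted
  miR-201  on tx001 291-311 (-) MFE  -45.1 kcal/mol -> accepted
  miR-202  on tx002 67-87 (+) MFE   -6.8 kcal/mol -> rejected (mfe_ok)
  miR-202  on tx002 102-122 (-) MFE  -17.2 kcal/mol -> rejected (mature_in_one_arm, mfe_ok)
families after redundancy removal: ['miR-201']
```

The compliant hairpin is accepted through both its mature and star arms
and collapses to one family; the engineered weak stem folds but misses
the −20 kcal/mol bound. The differential fixture analysis
(`python examples/03_differential_networks.py`) prints:

```
JH families: 11   JV families: 13
common: ['miR-156', 'miR-157', 'miR-159', 'miR-319', 'miR-4995', 'miR-5021', 'miR-5658', 'miR-f11908']
unique to JH: ['miR-172', 'miR-414', 'miR-529']
unique to JV: ['miR-2910', 'miR-2914', 'miR-477', 'miR-f11953', 'miR-f12158']
shared targets: 25 (16 up, 9 down in JV)
common-miRNA network: 61 nodes, 58 edges; hub miR-5021 (degree 26); degree correlation r = -0.62
query genes for co-expression: ['CMO', 'RPS5', 'RPL9', 'EIF5', 'MVA1', 'PPC', 'PSAX', 'SUMO', 'CYP707A1', 'DXS']
```

11 and 13 miRNA families with 8 shared, the condition-specific sets,
and the 10 query genes carried into co-expression reconstruction; the
negative r is the disassortative hub-to-leaf shape typical of regulator
networks.

The same stages are available from the shell:

```bash
mirframe simulate --seed 42 -o simdir
mirframe run-all --input-dir simdir -o results --flank 80
```

which writes per-stage TSV/SIF/GraphML outputs plus a manifest with the
seed and config digest.

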