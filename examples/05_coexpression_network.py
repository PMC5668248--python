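"""Weighted co-expression network around a query gene.

Generates a replicate FPKM table with a planted co-regulated pair
(latent-factor correlation 0.9), scores every candidate on abundance,
GO overlap and correlation, and keeps the top-k neighbors.
"""

from mirframe import (
    SimulationConfig,
    build_coexpression_network,
    make_expression,
)
from mirframe.coexpression import score_candidates, top_k_neighbors

config = SimulationConfig(
    seed=11,
    n_genes=15,
    n_replicates=10,
    coexpressed_groups=((("gene001", "gene002"), 0.9),),
)
expression = make_expression(config)

records = score_candidates("gene001", expression)
print("top 5 candidates for gene001 (weights 0.4 abundance / 0.3 GO / 0.3 PCC):")
for rec in top_k_neighbors("gene001", records, k=5):
    print(
        f"  {rec.candidate_gene}: abundance {rec.abundance_score:.2f}  "
        f"go {rec.go_score:.2f}  pcc {rec.pcc_score:.2f}  "
        f"combined {rec.combined:.3f}"
    )

network = build_coexpression_network(["gene001"], expression, k=5)
print(
    f"\nnetwork: {network.number_of_nodes()} nodes, "
    f"{network.number_of_edges()} edges (one query, k = 5)"
)
print(
    "\nThe planted partner gene002 carries a PCC component near 1"
    "\n((r + 1) / 2 with r ~ 0.9), lifting its combined score; without"
    "\nannotations the GO component is 0 for every candidate."
)
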