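"""GO node scores over a DAG and the score-inferred cluster network.

Builds a synthetic GO DAG with annotations, scores every transcript by
the decayed annotation total of its terms, and groups equal-score
transcripts into the cluster network.
"""

from mirframe import (
    SimulationConfig,
    cluster_by_score,
    make_go,
    node_score,
    score_transcripts,
)

config = SimulationConfig(seed=3, n_go_terms=15, dag_depth=3, n_annotations=25)
dag, annotations, truth = make_go(config)
gp = dict(zip(truth["go_term"], truth["gp"]))

root = next(t for t in dag.terms if not dag.parents(t))
for alpha in (1.0, 0.6, 0.3):
    print(f"root score at alpha={alpha}: {node_score(dag, root, gp, alpha):.2f}")
print(
    "(alpha = 1 counts every annotation below the root; smaller alpha"
    "\n discounts distant descendants per is_a edge)"
)

scores = score_transcripts(dag, annotations, alpha=0.6, namespace="BP")
network = cluster_by_score(scores, annotations=annotations)
print(f"\n{len(scores)} transcripts in {len(network.clusters)} score clusters:")
for cluster in network.clusters:
    print(
        f"  {cluster.label}: score {cluster.score:.2f}  "
        f"members {sorted(cluster.members)}"
    )
print(f"inter-cluster shared-term edges: {network.graph.number_of_edges()}")
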