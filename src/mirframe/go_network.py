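"""GO node scoring over a DAG and the score-inferred cluster network.

Each GO term g gets a node score aggregating annotation counts over its
descendant closure, decayed per edge of distance:

    score(g) = sum over g_a in desc(g) of gp(g_a) * alpha ** dist(g, g_a)

where desc(g) includes g itself at distance 0 (so a leaf's own
annotations count), gp(g_a) is the number of gene outcomes annotated to
g_a, dist is the shortest is_a path, and alpha in (0, 1] is the decay.
Transcripts are scored as the sum over their directly annotated terms,
grouped into clusters of equal score (within a relative tolerance), and
clusters are linked with edges weighted by the number of GO terms shared
between their members' annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

DEFAULT_ALPHA = 0.6
DEFAULT_TOLERANCE = 1e-9

NAMESPACES = ("BP", "MF", "CC")
_NAMESPACE_ALIASES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
    "": "",
}


class DagStructureError(ValueError):
    """The is_a graph is not a DAG; the message lists one cycle."""


class GoDag:
    """GO terms joined by child -> parent is_a edges, guaranteed acyclic."""

    def __init__(self, graph: nx.DiGraph):
        self._g = graph

    @classmethod
    def from_terms(cls, terms: dict, is_a_edges) -> "GoDag":
        g = nx.DiGraph()
        for term, info in terms.items():
            ns = _NAMESPACE_ALIASES.get(info.get("namespace", ""), info.get("namespace", ""))
            g.add_node(term, name=info.get("name", ""), namespace=ns)
        for child, parent in is_a_edges:
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise DagStructureError(f"is_a cycle detected: {path}")
        return cls(g)

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def terms(self) -> list:
        return list(self._g.nodes)

    def term_info(self, term: str) -> dict:
        return dict(self._g.nodes[term])

    def namespace(self, term: str) -> str:
        return self._g.nodes[term].get("namespace", "")

    def parents(self, term: str) -> set:
        return set(self._g.successors(term))

    def children(self, term: str) -> set:
        return set(self._g.predecessors(term))

    def descendants(self, term: str) -> set:
        """The descendant closure of a term, including the term itself."""
        if term not in self._g:
            raise KeyError(f"unknown GO term {term!r}")
        return nx.ancestors(self._g, term) | {term}

    def distances_down(self, term: str) -> dict:
        """Shortest descending is_a path length to every descendant."""
        if term not in self._g:
            raise KeyError(f"unknown GO term {term!r}")
        return nx.single_source_shortest_path_length(self._g.reverse(copy=False), term)

    def edges(self):
        return list(self._g.edges)


def node_score(dag: GoDag, term: str, gene_counts: dict, alpha: float = DEFAULT_ALPHA) -> float:
    """Decayed annotation total over the descendant closure of a term.

    ``gene_counts`` maps term -> gp (number of gene outcomes annotated to
    it); missing terms count 0. With alpha = 1 the score is exactly the
    subtree annotation total.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if term not in dag:
        raise KeyError(f"unknown GO term {term!r}")
    return sum(
        gene_counts.get(desc, 0) * alpha**dist
        for desc, dist in dag.distances_down(term).items()
    )


def annotation_counts(annotations, namespace: str = "", dag: GoDag | None = None) -> dict:
    """gp(term): number of distinct transcripts directly annotated to it."""
    dag = dag or annotations.dag
    counts: dict[str, int] = {}
    for _, term in annotations.pairs:
        if namespace and dag is not None and dag.namespace(term) != namespace:
            continue
        counts[term] = counts.get(term, 0) + 1
    return counts


def score_transcripts(
    dag: GoDag,
    annotations,
    alpha: float = DEFAULT_ALPHA,
    namespace: str = "",
) -> dict:
    """Per-transcript score: sum of node scores of its direct terms.

    gp counts are derived from the annotation set itself (annotations are
    already deduplicated pairs). Transcripts with no annotation in the
    namespace score 0.
    """
    if namespace and namespace not in NAMESPACES:
        raise ValueError(f"namespace must be one of {NAMESPACES}, got {namespace!r}")
    counts = annotation_counts(annotations, namespace, dag)
    term_scores = {
        term: node_score(dag, term, counts, alpha)
        for term in sorted({t for _, t in annotations.pairs})
        if not namespace or dag.namespace(term) == namespace
    }
    scores: dict[str, float] = {t: 0.0 for t in annotations.transcripts}
    for transcript, term in annotations.pairs:
        scores[transcript] += term_scores.get(term, 0.0)
    return scores


@dataclass
class GoCluster:
    label: str
    members: list  # transcript ids
    score: float  # representative (maximum member) score


@dataclass
class GoClusterNetwork:
    """Equal-score transcript clusters linked by shared-term edges."""

    clusters: list  # of GoCluster, descending score
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def transcripts(self) -> set:
        return {m for c in self.clusters for m in c.members}


def cluster_by_score(
    scores: dict,
    tolerance: float = DEFAULT_TOLERANCE,
    annotations=None,
) -> GoClusterNetwork:
    """Group transcripts whose scores agree within a relative tolerance.

    Scores are sorted descending and grouped greedily against the
    cluster's representative (first) score; |s - rep| <= tolerance *
    max(1, |rep|) joins the cluster. Inter-cluster edge weight = number
    of distinct GO terms annotating members on both sides. Cluster
    labels C1, C2, ... follow descending score.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    clusters: list[GoCluster] = []
    for transcript, score in ordered:
        if clusters:
            rep = clusters[-1].score
            if abs(score - rep) <= tolerance * max(1.0, abs(rep)):
                clusters[-1].members.append(transcript)
                continue
        clusters.append(
            GoCluster(label=f"C{len(clusters) + 1}", members=[transcript], score=score)
        )
    graph = nx.Graph()
    for c in clusters:
        graph.add_node(c.label, score=c.score, n_members=len(c.members))
    if annotations is not None:
        terms_of = {t: annotations.terms_for(t) for t in annotations.transcripts}
        for i, a in enumerate(clusters):
            terms_a = set().union(*(terms_of.get(m, set()) for m in a.members))
            for b in clusters[i + 1 :]:
                terms_b = set().union(*(terms_of.get(m, set()) for m in b.members))
                weight = len(terms_a & terms_b)
                if weight:
                    graph.add_edge(a.label, b.label, weight=weight)
    return GoClusterNetwork(clusters=clusters, graph=graph)


def filter_top_nodes(network: GoClusterNetwork, min_score: float = 0.0) -> GoClusterNetwork:
    """Keep clusters whose representative score reaches ``min_score``."""
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    kept = [c for c in network.clusters if c.score >= min_score]
    labels = {c.label for c in kept}
    return GoClusterNetwork(
        clusters=kept, graph=network.graph.subgraph(labels).copy()
    )
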