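"""Weighted co-expression network reconstruction.

For each query gene, every other expressed gene is scored on three
components, each normalized to [0, 1]:

* abundance — the candidate's mean FPKM, rank-normalized across the
  candidate pool;
* GO — Jaccard overlap of the query's and candidate's direct GO
  annotations;
* PCC — Pearson correlation of the two genes' replicate FPKM profiles,
  rescaled from [-1, 1] to [0, 1].

The combined score is the weighted sum with default weights 0.4 (abundance),
0.3 (GO), 0.3 (PCC), so a candidate maximal in all three scores exactly
1. Per query the top k (default 20) candidates by combined score become
its neighbors in the undirected co-expression network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (0.4, 0.3, 0.3)  # abundance, GO, PCC
DEFAULT_K = 20


@dataclass(frozen=True)
class CoexpressionRecord:
    """Component and combined scores for one query/candidate pair."""

    query_gene: str
    candidate_gene: str
    abundance_score: float
    go_score: float
    pcc_score: float
    weights: tuple = DEFAULT_WEIGHTS
    combined: float = 0.0


def check_weights(weights) -> tuple:
    w = tuple(float(x) for x in weights)
    if len(w) != 3 or any(x < 0 for x in w):
        raise ValueError("need three non-negative weights (abundance, GO, PCC)")
    if abs(sum(w) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(w)}")
    return w


def combined_score(components, weights=DEFAULT_WEIGHTS) -> float:
    """Weighted sum of (abundance, GO, PCC) component scores."""
    w = check_weights(weights)
    c = tuple(float(x) for x in components)
    if len(c) != 3:
        raise ValueError("need three component scores")
    return w[0] * c[0] + w[1] * c[1] + w[2] * c[2]


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def abundance_ranks(expression: pd.DataFrame, genes) -> dict:
    """Mean FPKM rank-normalized to [0, 1] over a gene pool.

    Average ranks for ties; a single-gene pool scores 1.0.
    """
    means = (
        expression[expression["transcript_id"].isin(set(genes))]
        .groupby("transcript_id")["fpkm"]
        .mean()
    )
    missing = set(genes) - set(means.index)
    if missing:
        raise ValueError(f"no expression for genes: {sorted(missing)[:5]}")
    if len(means) == 1:
        return {means.index[0]: 1.0}
    ranks = means.rank(method="average") - 1.0
    return (ranks / (len(means) - 1)).to_dict()


def replicate_profile(expression: pd.DataFrame, gene: str) -> np.ndarray:
    """FPKM vector over (condition, replicate), deterministically ordered."""
    sub = expression[expression["transcript_id"] == gene].sort_values(
        ["condition", "replicate"]
    )
    if sub.empty:
        raise ValueError(f"no expression for gene {gene!r}")
    return sub["fpkm"].to_numpy()


def pair_pcc(expression: pd.DataFrame, gene_a: str, gene_b: str) -> float:
    """Pearson correlation of two genes' replicate FPKM profiles."""
    a = replicate_profile(expression, gene_a)
    b = replicate_profile(expression, gene_b)
    if len(a) != len(b):
        raise ValueError(f"profile lengths differ for {gene_a!r}/{gene_b!r}")
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0  # no co-variation signal
    return float(stats.pearsonr(a, b)[0])


def component_scores(
    query: str,
    candidate: str,
    expression: pd.DataFrame,
    annotations=None,
    abundance: dict | None = None,
) -> tuple[float, float, float]:
    """(abundance, GO, PCC) scores for one query/candidate pair.

    ``abundance`` may carry precomputed rank scores for the candidate
    pool; otherwise the candidate pool is all expressed genes.
    """
    if abundance is None:
        abundance = abundance_ranks(
            expression, expression["transcript_id"].unique()
        )
    if candidate not in abundance:
        raise ValueError(f"no abundance score for gene {candidate!r}")
    a_score = _clip01(abundance[candidate])

    if annotations is None:
        go_score = 0.0
    else:
        terms_q = annotations.terms_for(query)
        terms_c = annotations.terms_for(candidate)
        union = terms_q | terms_c
        go_score = len(terms_q & terms_c) / len(union) if union else 0.0

    pcc = pair_pcc(expression, query, candidate)
    return a_score, go_score, _clip01((pcc + 1.0) / 2.0)


def top_k_neighbors(query: str, records, k: int = DEFAULT_K) -> list:
    """Best k candidates by (descending combined, ascending gene id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(records, key=lambda r: (-r.combined, r.candidate_gene))
    return ordered[:k]


def score_candidates(
    query: str,
    expression: pd.DataFrame,
    annotations=None,
    weights=DEFAULT_WEIGHTS,
    candidates=None,
) -> list:
    """CoexpressionRecords for every candidate of one query gene."""
    w = check_weights(weights)
    pool = sorted(
        set(candidates)
        if candidates is not None
        else set(expression["transcript_id"].unique()) - {query}
    )
    abundance = abundance_ranks(expression, pool)
    records = []
    for cand in pool:
        comp = component_scores(query, cand, expression, annotations, abundance)
        records.append(
            CoexpressionRecord(
                query_gene=query,
                candidate_gene=cand,
                abundance_score=comp[0],
                go_score=comp[1],
                pcc_score=comp[2],
                weights=w,
                combined=combined_score(comp, w),
            )
        )
    return records


def build_coexpression_network(
    queries,
    expression: pd.DataFrame,
    annotations=None,
    weights=DEFAULT_WEIGHTS,
    k: int = DEFAULT_K,
) -> nx.Graph:
    """Undirected network joining each query to its top-k candidates.

    Edge weight is the combined score; node attribute ``role`` marks
    query hubs (a gene that is both query and neighbor stays a query).
    """
    queries = list(queries)
    graph = nx.Graph(relation="coexpressed")
    if not queries:
        logger.warning("empty query set: returning empty co-expression network")
        return graph
    expressed = set(expression["transcript_id"].unique())
    missing = [q for q in queries if q not in expressed]
    if missing:
        raise ValueError(f"queries without expression: {missing[:5]}")
    for query in queries:
        records = score_candidates(query, expression, annotations, weights)
        graph.add_node(query, role="query")
        for rec in top_k_neighbors(query, records, k):
            if rec.candidate_gene not in graph:
                graph.add_node(rec.candidate_gene, role="neighbor")
            graph.add_edge(
                query, rec.candidate_gene, weight=round(rec.combined, 10)
            )
    for q in queries:  # queries drawn in as neighbors stay queries
        graph.nodes[q]["role"] = "query"
    return graph
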