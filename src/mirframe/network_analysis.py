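"""Bipartite miRNA-target networks and their degree/correlation profiles.

The interaction matrix A has A_ij = 1 exactly when miRNA i targets
transcript j; the bipartite network draws a directed edge miRNA -> target
for every 1 entry. Degrees, the degree distribution p(k) and the
endpoint-degree correlation are computed on the undirected view, since
neighborhood size does not depend on edge direction.

The degree correlation r is the Newman assortativity: every undirected
edge contributes its endpoint-degree pair symmetrized, and

    r = [<jk> - <(j+k)/2>^2] / [<(j^2+k^2)/2> - <(j+k)/2>^2]

over the 2M symmetrized pairs. r is undefined (NaN) when all endpoint
degrees are equal (zero variance), e.g. on regular graphs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FixtureTables
from .mirna_discovery import MiRNAInventory

logger = logging.getLogger(__name__)

UP, DOWN, UNCHANGED, UNKNOWN = "up", "down", "unchanged", "unknown"


@dataclass
class ConditionComparison:
    """Set algebra between two conditions' inventories plus regulation."""

    condition_a: str
    condition_b: str
    common_mirnas: set
    unique_mirnas: dict  # condition -> set
    common_targets: set
    unique_targets: dict  # condition -> set
    regulation: dict  # shared target -> (fpkm_a, fpkm_b, call)
    common_mirna_targets: set = field(default_factory=set)  # targets of shared miRNAs


def build_adjacency(pairs) -> pd.DataFrame:
    """0/1 interaction matrix over sorted unique miRNA/target labels."""
    pairs = list(pairs)
    mirnas = sorted({m for m, _ in pairs})
    targets = sorted({t for _, t in pairs})
    matrix = pd.DataFrame(
        np.zeros((len(mirnas), len(targets)), dtype=int),
        index=mirnas,
        columns=targets,
    )
    for m, t in pairs:
        matrix.loc[m, t] = 1
    return matrix


def build_bipartite(matrix: pd.DataFrame, condition: str = "") -> nx.DiGraph:
    """Directed miRNA -> target graph from an interaction matrix.

    miRNA nodes carry ``bipartite=0``, targets ``bipartite=1``; labels
    with no interactions are excluded.
    """
    g = nx.DiGraph(condition=condition, relation="targets")
    for mirna in matrix.index:
        row = matrix.loc[mirna]
        for target in matrix.columns[row.astype(bool)]:
            g.add_node(mirna, bipartite=0)
            g.add_node(target, bipartite=1)
            g.add_edge(mirna, target)
    return g


def network_variants(
    pairs_a, pairs_b, condition_a: str = "JH", condition_b: str = "JV"
) -> dict:
    """The three differential bipartite networks: unique to each
    condition, and the common-miRNA network with per-condition targets."""
    pairs_a, pairs_b = set(pairs_a), set(pairs_b)
    mirnas_a = {m for m, _ in pairs_a}
    mirnas_b = {m for m, _ in pairs_b}
    common = mirnas_a & mirnas_b
    variants = {
        f"{condition_a}_unique": build_bipartite(
            build_adjacency([p for p in pairs_a if p[0] not in common]),
            condition_a,
        ),
        f"{condition_b}_unique": build_bipartite(
            build_adjacency([p for p in pairs_b if p[0] not in common]),
            condition_b,
        ),
        "common": build_bipartite(
            build_adjacency(
                [p for p in pairs_a | pairs_b if p[0] in common]
            ),
            f"{condition_a}+{condition_b}",
        ),
    }
    return variants


def compare_conditions(
    inventory_a: MiRNAInventory,
    inventory_b: MiRNAInventory,
    expression: pd.DataFrame | None = None,
) -> ConditionComparison:
    """Common/unique miRNAs and targets, with up/down regulation calls.

    Regulation of a shared target is up iff FPKM rises from condition A
    to condition B, down iff it falls, unchanged on exact ties. FPKMs
    come from the inventories' own tables, or from ``expression``
    (condition means) when given. Shared targets without expression on
    both sides are flagged unknown with a warning.
    """
    a, b = inventory_a, inventory_b
    common_mirnas = a.family_names & b.family_names
    common_targets = a.targets & b.targets

    def fpkm_of(inv: MiRNAInventory, target: str) -> float | None:
        if expression is not None:
            sub = expression[
                (expression["transcript_id"] == target)
                & (expression["condition"] == inv.condition)
            ]
            return float(sub["fpkm"].mean()) if len(sub) else None
        return inv.target_fpkm.get(target)

    regulation = {}
    for target in sorted(common_targets):
        fa, fb = fpkm_of(a, target), fpkm_of(b, target)
        if fa is None or fb is None:
            logger.warning(
                "no expression for shared target %r; regulation unknown", target
            )
            call = UNKNOWN
        else:
            call = UP if fb > fa else (DOWN if fb < fa else UNCHANGED)
        regulation[target] = (fa, fb, call)

    return ConditionComparison(
        condition_a=a.condition,
        condition_b=b.condition,
        common_mirnas=common_mirnas,
        unique_mirnas={
            a.condition: a.family_names - b.family_names,
            b.condition: b.family_names - a.family_names,
        },
        common_targets=common_targets,
        unique_targets={
            a.condition: a.targets - b.targets,
            b.condition: b.targets - a.targets,
        },
        regulation=regulation,
        common_mirna_targets={
            t
            for m, t in (a.target_pairs | b.target_pairs)
            if m in common_mirnas
        },
    )


def inventories_from_fixtures(
    tables: FixtureTables,
) -> tuple[MiRNAInventory, MiRNAInventory]:
    """Per-condition inventories carrying the fixture target pairs/FPKMs."""
    invs = []
    for cond, target_col, fpkm_col in (
        ("JH", "jh_target", "jh_fpkm"),
        ("JV", "jv_target", "jv_fpkm"),
    ):
        pairs, fpkm = set(), {}
        for _, row in tables.common_targets.iterrows():
            if row[target_col]:
                pairs.add((row["mirna"], row[target_col]))
                fpkm[row[target_col]] = row[fpkm_col]
        sub = tables.unique_targets[tables.unique_targets["condition"] == cond]
        for _, row in sub.iterrows():
            pairs.add((row["mirna"], row["target"]))
            fpkm[row["target"]] = row["fpkm"]
        invs.append(
            MiRNAInventory(
                condition=cond,
                families={m: [] for m in sorted({m for m, _ in pairs})},
                target_pairs=frozenset(pairs),
                target_fpkm=fpkm,
            )
        )
    return invs[0], invs[1]


# ---------------------------------------------------------------------------
# Degree and correlation
# ---------------------------------------------------------------------------


@dataclass
class DegreeProfile:
    degree: dict  # node -> k
    distribution: dict  # k -> fraction of nodes with degree k


def degree_profile(network: nx.Graph) -> DegreeProfile:
    """Per-node degree (undirected view) and normalized p(k)."""
    und = network.to_undirected() if network.is_directed() else network
    degree = {n: d for n, d in und.degree()}
    n = len(degree)
    dist: dict[int, float] = {}
    for k in degree.values():
        dist[k] = dist.get(k, 0) + 1
    distribution = {k: c / n for k, c in sorted(dist.items())} if n else {}
    return DegreeProfile(degree=degree, distribution=distribution)


def degree_correlation(network: nx.Graph) -> float:
    """Endpoint-degree correlation r over the network's edges.

    Each undirected edge contributes both orderings of its endpoint
    degrees. Returns NaN (with a diagnostic) when the denominator is
    zero; raises on an edgeless graph.
    """
    und = network.to_undirected() if network.is_directed() else network
    if und.number_of_edges() == 0:
        raise ValueError("degree correlation needs at least one edge")
    deg = dict(und.degree())
    j, k = [], []
    for u, v in und.edges():
        j.extend((deg[u], deg[v]))
        k.extend((deg[v], deg[u]))
    j = np.asarray(j, dtype=float)
    k = np.asarray(k, dtype=float)
    mean_jk = float(np.mean(j * k))
    mean_half_sum = float(np.mean((j + k) / 2.0))
    mean_half_sq = float(np.mean((j * j + k * k) / 2.0))
    num = mean_jk - mean_half_sum**2
    den = mean_half_sq - mean_half_sum**2
    if den == 0:
        logger.info("degree correlation undefined: zero endpoint-degree variance")
        return math.nan
    return num / den


def expression_pcc(
    expression: pd.DataFrame,
    transcript_id: str,
    condition_a: str,
    condition_b: str,
) -> float:
    """Pearson correlation of one transcript's replicate FPKM vectors
    between two conditions (replicates matched by index).

    Needs >= 3 replicates per condition; zero-variance vectors give NaN
    with a diagnostic. For tables without replicates use
    :func:`cross_transcript_pcc`.
    """
    vecs = []
    for cond in (condition_a, condition_b):
        sub = expression[
            (expression["transcript_id"] == transcript_id)
            & (expression["condition"] == cond)
        ].sort_values("replicate")
        if len(sub) < 3:
            raise ValueError(
                f"transcript {transcript_id!r} has {len(sub)} replicates in "
                f"{cond}; per-transcript PCC needs >= 3 "
                "(use cross_transcript_pcc for single-value tables)"
            )
        vecs.append(sub["fpkm"].to_numpy())
    a, b = vecs
    if len(a) != len(b):
        raise ValueError("replicate counts differ between conditions")
    if np.std(a) == 0 or np.std(b) == 0:
        logger.info("PCC undefined for %r: zero variance", transcript_id)
        return math.nan
    return float(stats.pearsonr(a, b)[0])


def cross_transcript_pcc(
    expression: pd.DataFrame,
    transcript_ids,
    condition_a: str,
    condition_b: str,
) -> float:
    """PCC between the two conditions' mean-FPKM vectors over a
    transcript set (one value per transcript per condition)."""
    ids = sorted(transcript_ids)
    if len(ids) < 3:
        raise ValueError("cross-transcript PCC needs >= 3 transcripts")
    means = expression.groupby(["transcript_id", "condition"])["fpkm"].mean()
    a = np.array([means[(t, condition_a)] for t in ids])
    b = np.array([means[(t, condition_b)] for t in ids])
    if np.std(a) == 0 or np.std(b) == 0:
        return math.nan
    return float(stats.pearsonr(a, b)[0])


def select_pcc_genes(
    comparison: ConditionComparison,
    tables: FixtureTables | None = None,
    rule: str = "packaged",
    expression: pd.DataFrame | None = None,
    min_fpkm: float = 0.0,
) -> list[str]:
    """Select the query genes for co-expression analysis.

    Candidates are transcripts targeted by miRNAs in both conditions.
    Rules:

    * ``packaged``: keep candidates listed in the packaged
      co-expression fixture, matched through the symbol synonym table;
      returns symbols in fixture order. The published gene set is not
      reconstructible from any printed FPKM threshold, so the packaged
      rule is membership in the published set itself.
    * ``all``: every common-miRNA target (long names, sorted).
    * ``min_fpkm``: candidates whose FPKM passes ``min_fpkm`` in both
      conditions.
    """
    pool = comparison.common_mirna_targets
    if rule == "packaged":
        if tables is None:
            raise ValueError("rule 'packaged' needs the fixture tables")
        mapping = tables.symbol_to_target()
        return [
            sym
            for sym in tables.query_gene_symbols()
            if mapping.get(sym) in pool
        ]
    if rule == "all":
        return sorted(pool)
    if rule == "min_fpkm":
        out = []
        for t in sorted(pool):
            fa, fb, _ = comparison.regulation.get(t, (None, None, UNKNOWN))
            if fa is not None and fb is not None and fa >= min_fpkm and fb >= min_fpkm:
                out.append(t)
        return out
    raise ValueError(f"unknown selection rule {rule!r}")
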