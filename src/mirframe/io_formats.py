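"""Readers and writers for the external formats the pipeline touches.

Sequences are normalised to RNA space (T -> U, uppercase) on load, since
folding and duplex scoring operate on RNA. Networks are written with
deterministic (lexicographic) node and edge order so repeated runs are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGUN")

NETWORK_FORMATS = ("sif", "graphml", "tsv")


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named RNA sequence (transcript or mature miRNA)."""

    id: str
    sequence: str
    kind: str = "transcript"  # "transcript" | "mature_mirna"
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement_rna())


def read_fasta(path, kind: str = "transcript") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, normalising to RNA.

    The id is the first whitespace token of the header; the remainder is
    kept as ``description``. Raises :class:`ParseError` naming the line
    number for empty headers or records without sequence.
    """
    path = Path(path)
    # Pre-scan for structural problems so errors can name line numbers;
    # Bio.SeqIO silently tolerates empty records.
    header_line = None
    header_has_seq = False
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header_line is not None and not header_has_seq:
                    raise ParseError(f"{path}:{header_line}: record has no sequence")
                if not line[1:].strip():
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                rec_id = line[1:].split()[0]
                if rec_id in seen_ids:
                    raise ParseError(f"{path}:{lineno}: duplicate record id {rec_id!r}")
                seen_ids.add(rec_id)
                header_line, header_has_seq = lineno, False
            else:
                if header_line is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before any header")
                header_has_seq = True
    if header_line is not None and not header_has_seq:
        raise ParseError(f"{path}:{header_line}: record has no sequence")

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=normalize_rna(str(rec.seq)),
                kind=kind,
                description=rec.description[len(rec.id):].strip(),
            )
        )
    return records


def write_fasta(records, path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

EXPRESSION_COLUMNS = ["transcript_id", "condition", "replicate", "fpkm"]


def validate_expression(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EXPRESSION_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"expression table missing columns: {missing}")
    if (table["fpkm"] < 0).any():
        bad = table.loc[table["fpkm"] < 0, "transcript_id"].iloc[0]
        raise ParseError(f"negative FPKM for transcript {bad!r}")
    dup = table.duplicated(subset=["transcript_id", "condition", "replicate"])
    if dup.any():
        raise ParseError("duplicate (transcript_id, condition, replicate) rows")
    if table.empty:
        raise ParseError("expression table has no rows")
    return table


def read_expression_table(path) -> pd.DataFrame:
    """TSV with columns transcript_id, condition, replicate, fpkm."""
    table = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "condition": str})
    table["replicate"] = table["replicate"].astype(int)
    table["fpkm"] = table["fpkm"].astype(float)
    return validate_expression(table[EXPRESSION_COLUMNS])


def write_expression_table(table: pd.DataFrame, path) -> None:
    validate_expression(table).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO annotations (the DAG itself lives in go_network)
# ---------------------------------------------------------------------------


@dataclass
class GoAnnotationSet:
    """Deduplicated (transcript_id, go_term) pairs bound to a GO DAG."""

    pairs: frozenset
    dag: "object" = None  # go_network.GoDag

    @property
    def transcripts(self) -> set:
        return {t for t, _ in self.pairs}

    def terms_for(self, transcript_id: str) -> set:
        return {g for t, g in self.pairs if t == transcript_id}


def read_go_annotations(path, dag=None) -> GoAnnotationSet:
    """TSV with columns transcript_id, go_term; duplicates collapsed."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"transcript_id", "go_term"} <= set(table.columns):
        raise ParseError("annotation table needs columns transcript_id, go_term")
    pairs = frozenset(zip(table["transcript_id"], table["go_term"]))
    if dag is not None:
        unknown = {g for _, g in pairs if g not in dag}
        if unknown:
            raise ParseError(f"annotation references unknown GO terms: {sorted(unknown)[:5]}")
    return GoAnnotationSet(pairs=pairs, dag=dag)


def write_go_annotations(annotations: GoAnnotationSet, path) -> None:
    rows = sorted(annotations.pairs)
    pd.DataFrame(rows, columns=["transcript_id", "go_term"]).to_csv(
        path, sep="\t", index=False
    )


def read_obo_lite(path):
    """Parse a minimal OBO subset (id, name, namespace, is_a) into a GoDag.

    Other tags are ignored with a debug log line. A term whose is_a parent
    is never declared, or any directed cycle, raises :class:`ParseError`.
    """
    from .go_network import GoDag  # local import: go_network does not import us

    terms: dict[str, dict] = {}
    edges: list[tuple[str, str, int]] = []  # (child, parent, lineno)
    current = None
    in_term = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("["):
                in_term = line == "[Term]"
                current = None
                continue
            if not in_term or ":" not in line:
                continue
            tag, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            tag = tag.strip()
            if tag == "id":
                if not value:
                    raise ParseError(f"{path}:{lineno}: empty term id")
                current = value
                terms.setdefault(current, {"name": "", "namespace": ""})
            elif current is None:
                raise ParseError(f"{path}:{lineno}: {tag} before id in [Term] stanza")
            elif tag == "name":
                terms[current]["name"] = value
            elif tag == "namespace":
                terms[current]["namespace"] = value
            elif tag == "is_a":
                edges.append((current, value, lineno))
            else:
                logger.debug("OBO tag %r ignored (line %d)", tag, lineno)
    for child, parent, lineno in edges:
        if parent not in terms:
            raise ParseError(
                f"{path}:{lineno}: is_a parent {parent!r} is not a declared term"
            )
    return GoDag.from_terms(
        terms, [(c, p) for c, p, _ in edges]
    )  # raises ParseError listing any cycle


def write_obo_lite(dag, path) -> None:
    """Serialise a GoDag back to the minimal OBO subset (round-trippable)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            info = dag.term_info(term)
            fh.write(f"\n[Term]\nid: {term}\n")
            if info.get("name"):
                fh.write(f"name: {info['name']}\n")
            if info.get("namespace"):
                fh.write(f"namespace: {info['namespace']}\n")
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent}\n")


# ---------------------------------------------------------------------------
# Packaged fixture tables (differential miRNA/target transcriptions)
# ---------------------------------------------------------------------------


@dataclass
class FixtureTables:
    """Packaged transcriptions of the published JH/JV miRNA-target tables."""

    common_targets: pd.DataFrame
    unique_targets: pd.DataFrame
    coexpr_genes: pd.DataFrame
    synonyms: pd.DataFrame  # gene symbol -> long target name

    def mirna_families(self, condition: str) -> set[str]:
        """Families with at least one target in the given condition (JH/JV)."""
        if condition not in ("JH", "JV"):
            raise ValueError(f"condition must be JH or JV, got {condition!r}")
        col = "jh_target" if condition == "JH" else "jv_target"
        common = set(
            self.common_targets.loc[self.common_targets[col] != "", "mirna"]
        )
        unique = set(
            self.unique_targets.loc[
                self.unique_targets["condition"] == condition, "mirna"
            ]
        )
        return common | unique

    def common_mirna_families(self) -> set[str]:
        return self.mirna_families("JH") & self.mirna_families("JV")

    def unique_mirna_families(self, condition: str) -> set[str]:
        other = "JV" if condition == "JH" else "JH"
        return self.mirna_families(condition) - self.mirna_families(other)

    def symbol_to_target(self) -> dict[str, str]:
        return dict(zip(self.synonyms["symbol"], self.synonyms["target_name"]))

    def query_gene_symbols(self) -> list[str]:
        return list(self.coexpr_genes["gene"])


def _fixture_path(name: str):
    return resources.files("mirframe") / "fixtures" / name


def load_fixture_tables() -> FixtureTables:
    """Load the packaged fixture tables. Pure: repeated calls identical."""
    read = lambda name, **kw: pd.read_csv(
        _fixture_path(name), sep="\t", dtype=str, keep_default_na=False, **kw
    )
    common = read("common_targets.tsv")
    for col in ("jh_fpkm", "jv_fpkm"):
        common[col] = common[col].map(lambda v: float(v) if v else float("nan"))
    unique = read("unique_targets.tsv")
    unique["fpkm"] = unique["fpkm"].astype(float)
    return FixtureTables(
        common_targets=common,
        unique_targets=unique,
        coexpr_genes=read("coexpression_genes.tsv"),
        synonyms=read("synonyms.tsv"),
    )


def validate_fixture_regulation(tables: FixtureTables) -> list[str]:
    """Report rows whose printed regulation arrow disagrees with the FPKMs.

    The published table contains arrows inconsistent with their own FPKM
    values; the fixture stores the printed arrow verbatim and this check
    surfaces the disagreement instead of silently correcting it.
    """
    problems = []
    for _, row in tables.common_targets.iterrows():
        if row["regulation"] == "absent":
            continue
        jh, jv = row["jh_fpkm"], row["jv_fpkm"]
        numeric = "up" if jv > jh else ("down" if jv < jh else "unchanged")
        if numeric != row["regulation"]:
            problems.append(
                f"row {row['sno']} ({row['jh_target']}): printed {row['regulation']}, "
                f"FPKM {jh} -> {jv} implies {numeric}"
            )
    for msg in problems:
        logger.warning("fixture regulation discrepancy: %s", msg)
    return problems


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def _ordered_copy(graph: nx.Graph) -> nx.Graph:
    out = graph.__class__()
    for node in sorted(graph.nodes, key=str):
        out.add_node(node, **graph.nodes[node])
    for u, v in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
        out.add_edge(u, v, **graph.edges[u, v])
    return out


def write_network(graph: nx.Graph, path, format: str = "sif") -> None:
    """Write a network as SIF, GraphML, or an edge-list TSV.

    Node and edge order is lexicographic so output is deterministic. The
    bipartite side, if present, travels as the ``bipartite`` node attribute
    (GraphML) or is implicit in edge direction (SIF/TSV).
    """
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    ordered = _ordered_copy(graph)
    if fmt == "graphml":
        nx.write_graphml(ordered, str(path))
    elif fmt == "sif":
        relation = graph.graph.get("relation", "targets")
        with open(path, "w") as fh:
            isolated = []
            for u, v in ordered.edges:
                fh.write(f"{u}\t{relation}\t{v}\n")
            for node in ordered.nodes:
                if ordered.degree(node) == 0:
                    isolated.append(node)
            for node in isolated:
                fh.write(f"{node}\n")
    else:  # tsv edge list
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, data in ordered.edges(data=True):
                fh.write(f"{u}\t{v}\t{data.get('weight', 1)}\n")


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(str(path))
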