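"""Synthetic study inputs: transcriptomes with planted precursors and
target sites, layered GO DAGs with annotations, and replicate FPKM
tables with planted co-expression structure.

Every generator is driven by a single integer seed and is fully
deterministic. Planted precursors are engineered hairpins:

    [base clamp] mature [top clamp] loop [rc top] star [rc base]

where the clamps are G/C-rich duplex segments that anchor the intended
stem against random background pairing, and the star arm is the reverse
complement of the mature, modified per compliance profile:

* ``all_pass``      — perfect duplex, both clamps; passes all criteria.
* ``fail_mfe``      — A/U-only mature, short top clamp, no base clamp:
                      a genuine but weak hairpin above the MFE bound.
* ``fail_arm``      — star only complements the mature's 3' part, so six
                      5' mature bases sit outside the stem.
* ``fail_mismatches`` — seven non-pairing star substitutions (runs <= 2).
* ``fail_loop``     — star omits four central complements, bulging the
                      mature by an unpaired run of 4.

A truth table records every plant with its expected verdict so tests
can assert recovery without re-deriving ground truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .go_network import GoDag
from .io_formats import GoAnnotationSet, SequenceRecord, reverse_complement

PROFILES = ("all_pass", "fail_mfe", "fail_arm", "fail_mismatches", "fail_loop")

# which criterion flag each profile is engineered to break
PROFILE_FLAG = {
    "all_pass": None,
    "fail_mfe": "mfe_ok",
    "fail_arm": "mature_in_one_arm",
    "fail_mismatches": "duplex_mismatch_ok",
    "fail_loop": "no_loop_or_break",
}

# profiles whose verdict depends on weak or absent pairing are hosted in
# transcripts over {A, C}, which cannot pair with itself and so cannot
# invade the engineered stem or capture the dangling mature tail
_UNSTRUCTURED_HOST = {"fail_mfe", "fail_arm"}


@dataclass
class SimulationConfig:
    """Knobs for all generators; the seed fully determines every output."""

    seed: int = 42
    # transcriptome
    n_transcripts: int = 10
    transcript_length: tuple = (350, 450)
    planted_precursors: tuple = (("miR-101", "all_pass"),)
    planted_target_sites: tuple = ()  # family names; one perfect site each
    mature_length: int = 21
    clamp_length: int = 14
    loop_sequence: str = "ACACAA"
    # GO
    n_go_terms: int = 20
    dag_depth: int = 3
    n_annotations: int = 30
    # expression
    n_genes: int = 30
    n_replicates: int = 5
    conditions: tuple = ("JH", "JV")
    coexpressed_groups: tuple = ()  # ((gene, gene, ...), rho) entries
    shared_factor_scale: float = 0.4
    base_log_fpkm: float = 4.6  # ~ 100 FPKM
    log_fpkm_spread: float = 1.0

    def __post_init__(self):
        for _, profile in self.planted_precursors:
            if profile not in PROFILES:
                raise ValueError(f"unknown compliance profile {profile!r}")
        for _, rho in self.coexpressed_groups:
            if not (0 < rho <= 1):
                raise ValueError(f"planted correlation must be in (0, 1], got {rho}")


def _random_rna(rng: random.Random, length: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def _balanced_mature(
    rng: random.Random,
    length: int,
    gc_lo: float = 0.4,
    gc_hi: float = 0.7,
    alphabet: str = "ACGU",
) -> str:
    """Random mature with GC fraction inside [gc_lo, gc_hi]."""
    while True:
        seq = _random_rna(rng, length, alphabet)
        gc = (seq.count("G") + seq.count("C")) / length
        if gc_lo <= gc <= gc_hi:
            return seq


def _gc_clamp(rng: random.Random, length: int) -> str:
    return _random_rna(rng, length, alphabet="GC")


def build_precursor(
    rng: random.Random, mature: str, profile: str, config: SimulationConfig
) -> tuple[str, int]:
    """(precursor sequence, mature offset within it) for a profile."""
    loop = config.loop_sequence
    clamp = config.clamp_length
    if profile == "all_pass":
        base, top = _gc_clamp(rng, clamp), _gc_clamp(rng, clamp)
        seq = (
            base + mature + top + loop
            + reverse_complement(top)
            + reverse_complement(mature)
            + reverse_complement(base)
        )
        return seq, len(base)
    if profile == "fail_mfe":
        top = _gc_clamp(rng, 4)
        seq = mature + top + loop + reverse_complement(top) + reverse_complement(mature)
        return seq, 0
    if profile == "fail_arm":
        top = _gc_clamp(rng, clamp)
        stem_part = mature[6:]  # six 5' bases stay outside the stem
        seq = (
            mature + top + loop
            + reverse_complement(top)
            + reverse_complement(stem_part)
        )
        return seq, 0
    if profile == "fail_mismatches":
        # seven star substitutions (runs of <= 2) become 1:1 internal
        # loops: both arms keep the same length, so the flanking clamps
        # lock the pairing register. The mature for this profile is
        # U-free and every substituted star base faces an A, which pairs
        # only with U — so the mismatch faces cannot re-pair with any
        # mature base at any register offset. Clusters are spaced so
        # every interior paired run is >= 4 pairs and pays for its loops.
        positions = (2, 3, 8, 9, 14, 15, 20)
        base, top = _gc_clamp(rng, clamp), _gc_clamp(rng, clamp)
        broken = list(mature)
        for p in positions:
            broken[p] = "U"  # complement in the star arm is A
        star = reverse_complement("".join(broken))
        seq = (
            base + mature + top + loop + reverse_complement(top)
            + star + reverse_complement(base)
        )
        return seq, len(base)
    if profile == "fail_loop":
        base, top = _gc_clamp(rng, clamp), _gc_clamp(rng, clamp)
        bulged = mature[:9] + mature[13:]  # star skips four central bases
        seq = (
            base + mature + top + loop + reverse_complement(top)
            + reverse_complement(bulged) + reverse_complement(base)
        )
        return seq, len(base)
    raise ValueError(f"unknown compliance profile {profile!r}")


def make_transcriptome(config: SimulationConfig) -> dict:
    """Background transcripts with planted precursors and target sites.

    Returns ``transcripts`` and ``mature`` SequenceRecord lists plus a
    ``truth`` table listing every plant: kind (precursor/target_site),
    transcript, family, profile, mature/site coordinates and the
    criterion flag the plant is engineered to break (empty = accepted).
    """
    rng = random.Random(config.seed)
    lo, hi = config.transcript_length
    n_plants = len(config.planted_precursors) + len(config.planted_target_sites)
    if config.n_transcripts < n_plants:
        raise ValueError(
            f"{n_plants} plants need at least {n_plants} transcripts, "
            f"got {config.n_transcripts}"
        )

    # mature reference: one sequence per distinct family. The weak-stem
    # profile is A/U-only (no strong stacks); the arm profile starts with
    # six A's, which in an A/C host transcript cannot pair anywhere, so
    # the tail stays out of the stem by construction.
    families: dict[str, str] = {}
    for family, profile in config.planted_precursors:
        if family not in families:
            if profile == "fail_mfe":
                families[family] = _random_rna(rng, config.mature_length, "AU")
            elif profile == "fail_arm":
                families[family] = "AAAAAA" + _balanced_mature(
                    rng, config.mature_length - 6
                )
            elif profile == "fail_mismatches":
                # U-free and G/C-leaning: the interrupted duplex pays
                # for its internal loops, and A-faces at the mismatches
                # (A pairs only U) cannot re-pair with the mature. Each
                # paired segment between mismatch clusters must be G/C-
                # strong, else skipping it and merging its two loops
                # into one would cost less than its stacking gains.
                while True:
                    cand_seq = _balanced_mature(
                        rng, config.mature_length, 0.6, 0.8, alphabet="ACG"
                    )
                    gc = lambda s: sum(c in "GC" for c in s)
                    if (
                        gc(cand_seq[0:2]) >= 1
                        and all(
                            gc(cand_seq[a:b]) >= 3
                            for a, b in ((4, 8), (10, 14), (16, 20))
                        )
                    ):
                        break
                families[family] = cand_seq
            else:
                families[family] = _balanced_mature(rng, config.mature_length)
    for family in config.planted_target_sites:
        if family not in families:
            families[family] = _balanced_mature(rng, config.mature_length)

    transcripts, truth_rows = [], []
    plant_queue = [("precursor", f, p) for f, p in config.planted_precursors] + [
        ("target_site", f, "") for f in config.planted_target_sites
    ]
    for idx in range(config.n_transcripts):
        tx_id = f"tx{idx + 1:03d}"
        length = rng.randint(lo, hi)
        host_alphabet = "ACGU"
        if idx < len(plant_queue) and plant_queue[idx][2] in _UNSTRUCTURED_HOST:
            host_alphabet = "AC"
        seq = _random_rna(rng, length, host_alphabet)
        if idx < len(plant_queue):
            kind, family, profile = plant_queue[idx]
            if kind == "precursor":
                insert, mat_off = build_precursor(
                    rng, families[family], profile, config
                )
            else:
                insert, mat_off = reverse_complement(families[family]), 0
            if length < len(insert) + 40:
                raise ValueError(
                    f"transcript length {length} too short for a "
                    f"{len(insert)} nt plant"
                )
            pos = rng.randint(20, length - len(insert) - 20)
            seq = seq[:pos] + insert + seq[pos + len(insert):]
            start = pos + mat_off
            end = start + (
                config.mature_length if kind == "precursor" else len(insert)
            )
            truth_rows.append(
                {
                    "kind": kind,
                    "transcript_id": tx_id,
                    "family": family,
                    "profile": profile,
                    "start": start,
                    "end": end,
                    "precursor_start": pos,
                    "precursor_end": pos + len(insert),
                    "expected_failure": PROFILE_FLAG.get(profile) or ""
                    if kind == "precursor"
                    else "",
                }
            )
        transcripts.append(SequenceRecord(id=tx_id, sequence=seq, kind="transcript"))

    mature = [
        SequenceRecord(id=family, sequence=seq, kind="mature_mirna")
        for family, seq in sorted(families.items())
    ]
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "kind", "transcript_id", "family", "profile", "start", "end",
            "precursor_start", "precursor_end", "expected_failure",
        ],
    )
    return {"transcripts": transcripts, "mature": mature, "truth": truth}


def make_expression(config: SimulationConfig) -> pd.DataFrame:
    """Replicate FPKM table with planted co-expressed gene groups.

    Log-FPKM of a grouped gene = gene mean + s * shared factor + sigma *
    idiosyncratic noise, with sigma chosen per group so the latent
    log-scale correlation equals the requested rho
    (rho = s^2 / (s^2 + sigma^2)); ungrouped genes get independent noise
    of the same total variance. With rho = 1 profiles are exact scalar
    multiples, so their Pearson correlation is exactly 1.
    """
    if config.n_replicates < 3:
        raise ValueError("n_replicates must be >= 3")
    rng = np.random.default_rng(config.seed)
    genes = [f"gene{idx + 1:03d}" for idx in range(config.n_genes)]
    group_of: dict[str, int] = {}
    sigma_of: dict[int, float] = {}
    s = config.shared_factor_scale
    for g_idx, (members, rho) in enumerate(config.coexpressed_groups):
        for gene in members:
            if gene not in genes:
                raise ValueError(f"grouped gene {gene!r} not among generated genes")
            group_of[gene] = g_idx
        sigma_of[g_idx] = s * np.sqrt(max(0.0, 1.0 / rho - 1.0))
    base_sigma = s  # total spread for ungrouped genes

    gene_mean = {
        g: config.base_log_fpkm + config.log_fpkm_spread * rng.standard_normal()
        for g in genes
    }
    # condition effect shifts the mean, shared by all replicates
    cond_shift = {
        (g, c): 0.25 * rng.standard_normal()
        for g in genes
        for c in config.conditions
    }
    factors = {
        (g_idx, c, r): rng.standard_normal()
        for g_idx in sigma_of
        for c in config.conditions
        for r in range(1, config.n_replicates + 1)
    }
    rows = []
    for gene in genes:
        for cond in config.conditions:
            for rep in range(1, config.n_replicates + 1):
                # grouped genes carry no independent condition effect:
                # their profile correlation is the planted latent one
                mu = gene_mean[gene] + (
                    0.0 if gene in group_of else cond_shift[(gene, cond)]
                )
                if gene in group_of:
                    g_idx = group_of[gene]
                    z = (
                        s * factors[(g_idx, cond, rep)]
                        + sigma_of[g_idx] * rng.standard_normal()
                    )
                else:
                    z = base_sigma * rng.standard_normal()
                rows.append(
                    {
                        "transcript_id": gene,
                        "condition": cond,
                        "replicate": rep,
                        "fpkm": float(np.exp(mu + z)),
                    }
                )
    return pd.DataFrame(rows)


def make_go(config: SimulationConfig) -> tuple[GoDag, GoAnnotationSet, pd.DataFrame]:
    """Layered random GO DAG plus annotations drawn over its leaves.

    Terms are spread over ``dag_depth`` + 1 layers under a single root;
    each term below the root gets one or two parents from the layer
    above, which makes the graph acyclic by construction. Annotations
    pair synthetic transcripts with leaf-layer terms; the truth table
    reports the direct annotation count gp per term.
    """
    if config.dag_depth < 1:
        raise ValueError("dag_depth must be >= 1")
    if config.n_go_terms < config.dag_depth + 1:
        raise ValueError("need at least one term per layer")
    rng = random.Random(config.seed + 1)
    term_ids = [f"GO:{idx + 1:07d}" for idx in range(config.n_go_terms)]
    layers: list[list[str]] = [[term_ids[0]]]
    remaining = term_ids[1:]
    per_layer = max(1, len(remaining) // config.dag_depth)
    for d in range(config.dag_depth):
        chunk = (
            remaining[d * per_layer : (d + 1) * per_layer]
            if d < config.dag_depth - 1
            else remaining[d * per_layer :]
        )
        if chunk:
            layers.append(chunk)
    terms = {
        t: {"name": f"synthetic term {t[-3:]}", "namespace": "BP"}
        for t in term_ids
    }
    edges = []
    for upper, lower in zip(layers, layers[1:]):
        for term in lower:
            parents = rng.sample(upper, k=min(len(upper), rng.choice((1, 1, 2))))
            for p in parents:
                edges.append((term, p))
    dag = GoDag.from_terms(terms, edges)

    leaves = layers[-1]
    pairs = set()
    transcripts = [f"tx{idx + 1:03d}" for idx in range(max(1, config.n_transcripts))]
    while len(pairs) < min(
        config.n_annotations, len(leaves) * len(transcripts)
    ):
        pairs.add((rng.choice(transcripts), rng.choice(leaves)))
    annotations = GoAnnotationSet(pairs=frozenset(pairs), dag=dag)
    gp: dict[str, int] = {}
    for _, term in pairs:
        gp[term] = gp.get(term, 0) + 1
    truth = pd.DataFrame(
        sorted(gp.items()), columns=["go_term", "gp"]
    )
    return dag, annotations, truth
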