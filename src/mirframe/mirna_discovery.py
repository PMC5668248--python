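"""Homology-based miRNA discovery with hairpin-criteria validation.

Candidate mature-miRNA sites are found by scanning every transcript window
(both strands) against a mature reference, filtered by mismatch count and
a simple occurrence-expectation e-value. Each match is expanded to a
precursor window, folded, and judged against six acceptance criteria:

1. the window was selected as a candidate precursor,
2. it folds into a stem-loop hairpin (>= ``min_stem_pairs`` pairs on the
   stem path enclosing a single terminal loop),
3. the mature sequence sits in one arm of that hairpin,
4. fewer than ``max_duplex_mismatches`` mature positions fail to pair
   with the opposite arm,
5. no mature base lies in the terminal loop and no unpaired run >= 3
   splits the mature pairing block,
6. the window minimum free energy is at or below ``mfe_threshold``
   kcal/mol (default -20).

Matches with zero mismatches inherit the reference family name; matches
with 1..max_mismatches are retained as putative/novel candidates and
given miR-f-style family names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io_formats import SequenceRecord, reverse_complement
from .rna_fold import (
    FIVE_PRIME_ARM,
    LOOP,
    THREE_PRIME_ARM,
    FoldResult,
    LoopSpanError,
    arm_of,
    duplex_mismatches,
    fold,
    maximal_stem,
)

DEFAULT_EVALUE_CUTOFF = 1e-5
DEFAULT_MAX_MISMATCHES = 4
DEFAULT_FLANK = 120
DEFAULT_MFE_THRESHOLD = -20.0
DEFAULT_MAX_DUPLEX_MISMATCHES = 7
DEFAULT_MIN_STEM_PAIRS = 12

CRITERIA_NAMES = (
    "is_candidate",
    "has_hairpin",
    "mature_in_one_arm",
    "duplex_mismatch_ok",
    "no_loop_or_break",
    "mfe_ok",
)


@dataclass(frozen=True)
class MatureMatch:
    """A mature-miRNA homology hit on a transcript (forward coordinates)."""

    transcript_id: str
    mature_family: str
    start: int  # 0-based half-open on the forward strand
    end: int
    mismatches: int
    evalue: float
    strand: str = "+"  # orientation of the mature copy on the transcript

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PrecursorCandidate:
    """A precursor window around a mature match, with fold and verdicts."""

    match: MatureMatch
    window_start: int
    window_end: int
    window_sequence: str  # oriented so the mature appears in sense
    mature_offset: int  # mature start within window_sequence
    fold: FoldResult | None = None
    criteria: dict = field(default_factory=dict)

    @property
    def mature_span(self) -> tuple[int, int]:
        return (self.mature_offset, self.mature_offset + self.match.length)

    @property
    def accepted(self) -> bool:
        return bool(self.criteria) and all(
            self.criteria[name] for name in CRITERIA_NAMES
        )


@dataclass
class MiRNAInventory:
    """Accepted miRNA families for one condition, redundancy removed."""

    condition: str
    families: dict  # family name -> list of supporting PrecursorCandidates
    target_pairs: frozenset = frozenset()  # optional (family, target) pairs
    target_fpkm: dict = field(default_factory=dict)

    @property
    def family_names(self) -> set:
        return set(self.families)

    @property
    def targets(self) -> set:
        return {t for _, t in self.target_pairs}


def family_name(reference_name: str) -> str:
    """Collapse a mature name to its family (ath-miR156a -> miR-156).

    miR-f-style novel identifiers keep their full numeric id.
    """
    m = re.search(r"miR-?f(\d+)", reference_name, flags=re.IGNORECASE)
    if m:
        return f"miR-f{m.group(1)}"
    m = re.search(r"miR-?(\d+)", reference_name, flags=re.IGNORECASE)
    if m:
        return f"miR-{m.group(1)}"
    return reference_name


def occurrence_evalue(
    database_length: int, transcript_length: int, matched_positions: int
) -> float:
    """Expected chance occurrences: db_len * tx_len * 4^-matched_positions.

    A plain occurrence expectation, not a Karlin-Altschul statistic; the
    pipeline only needs a monotone filter against a fixed cutoff.
    """
    return database_length * transcript_length * 4.0 ** (-matched_positions)


def _hamming_within(a: str, b: str, budget: int) -> int | None:
    """Mismatch count if <= budget, else None (early exit)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return None
    return mm


def find_mature_matches(
    transcripts,
    mature_reference,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[MatureMatch]:
    """Scan every transcript window on both strands against each mature.

    Matches with more than ``max_mismatches`` mismatches or with e-value
    above ``evalue_cutoff`` are dropped; the rest are returned sorted by
    (transcript_id, start, family).
    """
    for mat in mature_reference:
        if len(mat.sequence) < 15:
            raise ValueError(
                f"mature sequence {mat.id!r} shorter than 15 nt "
                f"({len(mat.sequence)} nt)"
            )
    database_length = sum(len(t.sequence) for t in transcripts)
    matches = []
    for tx in transcripts:
        seq = tx.sequence
        n = len(seq)
        strands = (("+", seq), ("-", reverse_complement(seq)))
        for mat in mature_reference:
            L = len(mat.sequence)
            if L > n:
                continue
            for strand, s in strands:
                for i in range(n - L + 1):
                    mm = _hamming_within(s[i : i + L], mat.sequence, max_mismatches)
                    if mm is None:
                        continue
                    ev = occurrence_evalue(database_length, n, L - mm)
                    if ev > evalue_cutoff:
                        continue
                    if strand == "+":
                        start, end = i, i + L
                    else:
                        start, end = n - (i + L), n - i
                    matches.append(
                        MatureMatch(
                            transcript_id=tx.id,
                            mature_family=family_name(mat.id),
                            start=start,
                            end=end,
                            mismatches=mm,
                            evalue=ev,
                            strand=strand,
                        )
                    )
    matches.sort(key=lambda m: (m.transcript_id, m.start, m.mature_family, m.strand))
    return matches


def extract_precursor(
    transcript: SequenceRecord, match: MatureMatch, flank: int = DEFAULT_FLANK
) -> PrecursorCandidate:
    """Cut the precursor window [start-flank, end+flank) around a match.

    For minus-strand matches the window sequence is reverse-complemented
    so the mature copy always reads in sense; window coordinates stay on
    the forward strand.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    n = len(transcript.sequence)
    w_start = max(0, match.start - flank)
    w_end = min(n, match.end + flank)
    window = transcript.sequence[w_start:w_end]
    if match.strand == "+":
        offset = match.start - w_start
    else:
        window = reverse_complement(window)
        offset = w_end - match.end
    return PrecursorCandidate(
        match=match,
        window_start=w_start,
        window_end=w_end,
        window_sequence=window,
        mature_offset=offset,
    )


def _max_unpaired_run_in_block(candidate: PrecursorCandidate) -> int:
    """Longest run of unpaired bases strictly inside the mature pairing
    block (between the first and last paired mature positions)."""
    start, end = candidate.mature_span
    pt = candidate.fold.pair_table
    paired = [p for p in range(start, end) if pt[p] is not None]
    if len(paired) < 2:
        return end - start
    run = best = 0
    for p in range(paired[0], paired[-1] + 1):
        if pt[p] is None:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def evaluate_criteria(
    candidate: PrecursorCandidate,
    mfe_threshold: float = DEFAULT_MFE_THRESHOLD,
    max_duplex_mismatches: int = DEFAULT_MAX_DUPLEX_MISMATCHES,
    min_stem_pairs: int = DEFAULT_MIN_STEM_PAIRS,
    fold_backend=fold,
) -> PrecursorCandidate:
    """Fold the window (if not already folded) and fill the six verdicts."""
    if candidate.fold is None:
        candidate.fold = fold_backend(candidate.window_sequence)
    result = candidate.fold
    start, end = candidate.mature_span

    stem = maximal_stem(result)
    has_hairpin = stem is not None and stem["n_pairs"] >= min_stem_pairs

    arms = [arm_of(p, result) for p in range(start, end)]
    arm_kinds = {a for a in arms if a in (FIVE_PRIME_ARM, THREE_PRIME_ARM)}
    mature_in_one_arm = (
        len(arm_kinds) == 1
        and LOOP not in arms
        and all(a in arm_kinds for a in arms)
    )

    try:
        duplex_ok = duplex_mismatches((start, end), result) < max_duplex_mismatches
    except LoopSpanError:
        duplex_ok = False  # one-arm criterion already records the violation

    no_loop_or_break = (
        LOOP not in arms and _max_unpaired_run_in_block(candidate) < 3
    )

    candidate.criteria = {
        "is_candidate": True,
        "has_hairpin": has_hairpin,
        "mature_in_one_arm": mature_in_one_arm,
        "duplex_mismatch_ok": duplex_ok,
        "no_loop_or_break": no_loop_or_break,
        "mfe_ok": result.mfe <= mfe_threshold,
    }
    return candidate


def discover(
    transcripts,
    mature_reference,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    flank: int = DEFAULT_FLANK,
    mfe_threshold: float = DEFAULT_MFE_THRESHOLD,
    max_duplex_mismatches: int = DEFAULT_MAX_DUPLEX_MISMATCHES,
    min_stem_pairs: int = DEFAULT_MIN_STEM_PAIRS,
    fold_backend=fold,
) -> list[PrecursorCandidate]:
    """Full discovery pass: match, extract, fold, judge. One candidate per
    (transcript, site, family); overlapping same-family hits keep the
    lowest-mismatch one."""
    by_tx = {t.id: t for t in transcripts}
    matches = find_mature_matches(
        transcripts, mature_reference, max_mismatches, evalue_cutoff
    )
    kept: list[MatureMatch] = []
    for m in matches:  # suppress overlapping same-family hits
        drop = False
        for i, prev in enumerate(kept):
            if (
                prev.transcript_id == m.transcript_id
                and prev.mature_family == m.mature_family
                and m.start < prev.end
                and prev.start < m.end
            ):
                if m.mismatches < prev.mismatches:
                    kept[i] = m
                drop = True
                break
        if not drop:
            kept.append(m)
    out = []
    for m in kept:
        cand = extract_precursor(by_tx[m.transcript_id], m, flank)
        out.append(
            evaluate_criteria(
                cand,
                mfe_threshold=mfe_threshold,
                max_duplex_mismatches=max_duplex_mismatches,
                min_stem_pairs=min_stem_pairs,
                fold_backend=fold_backend,
            )
        )
    return out


def build_inventory(accepted_candidates, condition_label: str) -> MiRNAInventory:
    """Collapse accepted candidates into unique families per condition.

    Zero-mismatch candidates keep the reference family; candidates that
    matched with mismatches are putative/novel and renamed miR-f<digits>
    from the reference family digits.
    """
    families: dict[str, list] = {}
    for cand in accepted_candidates:
        fam = cand.match.mature_family
        if cand.match.mismatches > 0 and not fam.startswith("miR-f"):
            fam = "miR-f" + fam.removeprefix("miR-")
        families.setdefault(fam, []).append(cand)
    ordered = {name: families[name] for name in sorted(families)}
    return MiRNAInventory(condition=condition_label, families=ordered)
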