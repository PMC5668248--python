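"""miRNA target scoring in the psRNATarget tradition.

A miRNA is aligned antiparallel against candidate transcript sites; each
miRNA position contributes a penalty (match 0, G:U wobble 0.5, mismatch
1.0, gap 2.0), doubled inside the core region (miRNA positions 2-13 from
the 5' end). Only the first ``upsize`` (default 20) miRNA positions are
scored. The per-site expectation is the total penalty; sites above the
expectation cutoff (default 3) are discarded and at most ``top_n``
(default 200) sites are reported per miRNA.

A central *mismatch* at miRNA positions 9-11 calls the site translational
inhibition; everything else is cleavage. Wobbles at 9-11 do not trigger
the inhibition call by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

from .rna_fold import fold as _builtin_fold

MATCH, MISMATCH, WOBBLE, GAP = "match", "mismatch", "wobble", "gap"
CLEAVAGE, TRANSLATIONAL_INHIBITION = "cleavage", "translational_inhibition"

DEFAULT_MAX_EXPECTATION = 3.0
DEFAULT_TOP_N = 200
DEFAULT_UPSIZE = 20
DEFAULT_CORE = (2, 13)
DEFAULT_CENTRAL_RANGE = (9, 11)
DEFAULT_FLANK_UP = 17
DEFAULT_FLANK_DOWN = 13

PENALTIES = {MATCH: 0.0, WOBBLE: 0.5, MISMATCH: 1.0, GAP: 2.0}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class TargetAlignment:
    """A scored miRNA/mRNA duplex at one transcript site."""

    mirna_family: str
    transcript_id: str
    site_start: int  # 0-based half-open transcript coordinates
    site_end: int
    states: tuple  # per miRNA position 1..L from the 5' end
    expectation: float
    mode: str

    def alignment_string(self) -> str:
        glyph = {MATCH: "|", WOBBLE: "o", MISMATCH: "x", GAP: "-"}
        return "".join(glyph[s] for s in self.states)


def _pair_state(m: str, t: str) -> str:
    """State of miRNA base m facing target base t (antiparallel duplex)."""
    if _COMPLEMENT.get(m) == t:
        return MATCH
    if (m, t) in (("G", "U"), ("U", "G")):
        return WOBBLE
    return MISMATCH


def score_duplex(
    mirna: str,
    site: str,
    upsize: int = DEFAULT_UPSIZE,
    core: tuple = DEFAULT_CORE,
    core_double: bool = True,
    max_gaps: int = 1,
    penalties: dict = PENALTIES,
) -> tuple[tuple, float]:
    """Best (states, expectation) aligning the miRNA against one site.

    ``site`` is the transcript subsequence 5'->3'; the miRNA binds it
    antiparallel, so miRNA position 1 faces the site's 3' end. With at
    most one gap the site length must be within one of the miRNA length.
    All gap placements are scanned exhaustively and the minimum-
    expectation alignment (ties: fewer gaps, then 5'-most gap) wins.
    Positions beyond ``upsize`` are reported but carry no penalty.
    """
    if len(mirna) < 15:
        raise ValueError(f"miRNA shorter than 15 nt ({len(mirna)} nt)")
    L = len(mirna)
    rev = site[::-1]  # rev[p-1] faces miRNA position p
    S = len(rev)
    if not (L - max_gaps <= S <= L + max_gaps):
        raise ValueError(
            f"site length {S} incompatible with miRNA length {L} "
            f"and {max_gaps} allowed gap(s)"
        )

    def weight(pos: int, state: str) -> float:
        pen = penalties[state]
        if pos > upsize:
            return 0.0
        if core_double and core[0] <= pos <= core[1]:
            return pen * 2
        return pen

    def ungapped(m_seq: str, s_seq: str, offset: int = 0):
        states, total = [], 0.0
        for k, (m, t) in enumerate(zip(m_seq, s_seq)):
            st = _pair_state(m, t)
            states.append(st)
            total += weight(offset + k + 1, st)
        return states, total

    candidates = []  # (expectation, n_gaps, gap_pos, states)
    if S == L:
        states, total = ungapped(mirna, rev)
        candidates.append((total, 0, 0, tuple(states)))
    elif S == L - 1:
        # one miRNA base faces a gap in the site
        for g in range(1, L + 1):
            left_s, left_t = ungapped(mirna[: g - 1], rev[: g - 1])
            right_s, right_t = ungapped(mirna[g:], rev[g - 1 :], offset=g)
            states = tuple(left_s + [GAP] + right_s)
            total = left_t + weight(g, GAP) + right_t
            candidates.append((total, 1, g, states))
    else:  # S == L + 1: one site base faces a gap in the miRNA
        for g in range(1, L + 2):  # g = L + 1 leaves the 5'-most site base unopposed
            left_s, left_t = ungapped(mirna[: g - 1], rev[: g - 1])
            right_s, right_t = ungapped(mirna[g - 1 :], rev[g:], offset=g - 1)
            states = tuple(left_s + right_s)
            total = left_t + weight(g, GAP) + right_t
            candidates.append((total, 1, g, states))
    best = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    return best[3], best[0]


def classify_mode(
    states,
    central_range: tuple = DEFAULT_CENTRAL_RANGE,
    wobble_counts: bool = False,
) -> str:
    """Translational inhibition iff a central mismatch falls in
    ``central_range`` (1-based miRNA positions); else cleavage."""
    triggers = {MISMATCH, WOBBLE} if wobble_counts else {MISMATCH}
    lo, hi = central_range
    for pos in range(lo, min(hi, len(states)) + 1):
        if states[pos - 1] in triggers:
            return TRANSLATIONAL_INHIBITION
    return CLEAVAGE


def _anchor_passes_prescan(
    mirna: str,
    seq: str,
    start: int,
    upsize: int,
    core_double: bool,
    max_gaps: int,
    bound: float,
) -> bool:
    """Early-abandoned ungapped scan of each candidate 3'-end register.

    The miRNA 5' prefix of any alignment (gapped or not) coincides with
    the ungapped register sharing its site 3' end, so an anchor can only
    host a passing site if one register scores within ``bound``."""
    L = len(mirna)
    for S in range(L - max_gaps, L + max_gaps + 1):
        site_end = start + S
        if site_end > len(seq) or S < 1:
            continue
        total = 0.0
        for p in range(1, min(upsize, S) + 1):
            st = _pair_state(mirna[p - 1], seq[site_end - p])
            pen = PENALTIES[st]
            if core_double and DEFAULT_CORE[0] <= p <= DEFAULT_CORE[1]:
                pen *= 2
            total += pen
            if total > bound:
                break
        if total <= bound:
            return True
    return False


def _best_site_at(mirna, seq, start, core_double, upsize, max_gaps):
    """Best alignment among site lengths L-1, L, L+1 anchored at start."""
    L = len(mirna)
    best = None
    for S in (L, L - 1, L + 1):
        if max_gaps == 0 and S != L:
            continue
        if start + S > len(seq) or S < 1:
            continue
        site = seq[start : start + S]
        states, exp = score_duplex(
            mirna, site, upsize=upsize, core_double=core_double, max_gaps=max_gaps
        )
        key = (exp, abs(S - L), S)
        if best is None or key < best[0]:
            best = (key, S, states, exp)
    return best


def predict_targets(
    mirnas: dict,
    transcripts,
    max_expectation: float = DEFAULT_MAX_EXPECTATION,
    top_n: int = DEFAULT_TOP_N,
    upsize: int = DEFAULT_UPSIZE,
    core_double: bool = True,
    max_gaps: int = 1,
    central_range: tuple = DEFAULT_CENTRAL_RANGE,
) -> list[TargetAlignment]:
    """Scan transcripts for target sites of each miRNA.

    ``mirnas`` maps family name -> mature sequence. Every anchor position
    is scored, overlapping sites are collapsed to the local best
    (ascending expectation, then transcript id and site start), and per
    miRNA the surviving sites are sorted ascending and cut to ``top_n``.
    """
    if max_expectation < 0:
        raise ValueError("max_expectation must be >= 0")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    # Anchors are pre-screened with an early-abandoned ungapped score.
    # A gap inside the doubled core costs 4 and alone exceeds the default
    # cutoff, so any passing gapped site has its gap 3' of the core and
    # its ungapped register scores at most cutoff + gap + post-core
    # mismatches worse: the bound below never prunes a passing site.
    prune_bound = (
        max_expectation
        + PENALTIES[GAP]
        + max(0, upsize - DEFAULT_CORE[1]) * PENALTIES[MISMATCH]
    )
    results = []
    for family in sorted(mirnas):
        mature = mirnas[family]
        hits = []
        for tx in sorted(transcripts, key=lambda t: t.id):
            seq = tx.sequence
            L = len(mature)
            for start in range(0, len(seq) - (L - 1)):
                if not _anchor_passes_prescan(
                    mature, seq, start, upsize, core_double, max_gaps, prune_bound
                ):
                    continue
                best = _best_site_at(
                    mature, seq, start, core_double, upsize, max_gaps
                )
                if best is None or best[3] > max_expectation:
                    continue
                _, S, states, exp = best
                hits.append(
                    TargetAlignment(
                        mirna_family=family,
                        transcript_id=tx.id,
                        site_start=start,
                        site_end=start + S,
                        states=states,
                        expectation=exp,
                        mode=classify_mode(states, central_range),
                    )
                )
        # ties prefer the gap-free site length: an unscored trailing gap
        # (beyond upsize) must not displace the exact site by one base
        hits.sort(
            key=lambda h: (
                h.expectation,
                h.transcript_id,
                abs((h.site_end - h.site_start) - L),
                h.site_start,
            )
        )
        chosen: list[TargetAlignment] = []
        for h in hits:  # greedy non-overlap suppression per transcript
            if any(
                c.transcript_id == h.transcript_id
                and h.site_start < c.site_end
                and c.site_start < h.site_end
                for c in chosen
            ):
                continue
            chosen.append(h)
            if len(chosen) >= top_n:
                break
        results.extend(chosen)
    return results


def site_flanks(
    transcript,
    site: tuple[int, int],
    up: int = DEFAULT_FLANK_UP,
    down: int = DEFAULT_FLANK_DOWN,
) -> str:
    """Target site plus up/down flanking bases, clipped at the bounds.

    Feeds the optional accessibility hook; defaults 17 upstream and 13
    downstream.
    """
    if up < 0 or down < 0:
        raise ValueError("flank lengths must be >= 0")
    start, end = site
    seq = transcript.sequence
    return seq[max(0, start - up) : min(len(seq), end + down)]


def site_unpairing_energy(
    transcript,
    site: tuple[int, int],
    up: int = DEFAULT_FLANK_UP,
    down: int = DEFAULT_FLANK_DOWN,
    fold_backend=_builtin_fold,
) -> float:
    """Optional accessibility hook: energy cost of opening the site.

    Folds the flanked window freely, then with every site base forced
    unpaired (site bases masked to N, which cannot pair), and returns the
    energy difference. OFF by default in the pipeline because the
    built-in model's absolute scale is not comparable to RNAup-style UPE
    thresholds.
    """
    start, end = site
    window = site_flanks(transcript, site, up, down)
    w_start = max(0, start - up)
    free = fold_backend(window).mfe
    masked = (
        window[: start - w_start]
        + "N" * (end - start)
        + window[end - w_start :]
    )
    constrained = fold_backend(masked).mfe
    return constrained - free
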