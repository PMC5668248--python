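"""Independent brute-force oracles used by the test suite.

These re-derive expected values by exhaustive enumeration and must stay
independent of the implementation paths they check: they import model
*parameters* (the published penalty/stacking constants) but none of the
dynamic-programming or scoring code.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

from mirframe.rna_fold import (
    HAIRPIN_PENALTY_KCAL,
    INTERNAL_PENALTY_KCAL,
    MAX_INTERNAL_UNPAIRED,
    MIN_HAIRPIN_LOOP,
    MULTILOOP_PENALTY_KCAL,
    STACKING_KCAL,
)

_PAIRS = {"AU", "UA", "CG", "GC", "GU", "UG"}

_H10 = round(HAIRPIN_PENALTY_KCAL * 10)
_I10 = round(INTERNAL_PENALTY_KCAL * 10)
_M10 = round(MULTILOOP_PENALTY_KCAL * 10)
_S10 = {k: round(v * 10) for k, v in STACKING_KCAL.items()}


def enumerate_structures(seq: str):
    """All nested pair sets with hairpin loops >= MIN_HAIRPIN_LOOP."""
    n = len(seq)

    memo: dict[tuple[int, int], list[frozenset]] = {}

    def rec(i: int, j: int) -> list[frozenset]:
        if i > j:
            return [frozenset()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [frozenset(s) for s in rec(i + 1, j)]  # i unpaired
        for l in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if seq[i] + seq[l] not in _PAIRS:
                continue
            for inner in rec(i + 1, l - 1):
                for rest in rec(l + 1, j):
                    out.append(inner | rest | {(i, l)})
        memo[key] = out
        return out

    return rec(0, n - 1)


def structure_energy10(seq: str, pairs: frozenset) -> int | None:
    """Loop-decomposition energy in tenths; None if the structure is not
    formable under the model (two-loop larger than the cap)."""
    by_open = sorted(pairs)
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in by_open}
    stack: list[tuple[int, int]] = []
    for p in by_open:
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        if stack:
            children[stack[-1]].append(p)
        stack.append(p)
    total = 0
    for (i, j), kids in children.items():
        if not kids:
            total += _H10
        elif len(kids) == 1:
            (k, l) = kids[0]
            unpaired = (k - i - 1) + (j - l - 1)
            if unpaired == 0:
                total += _S10[seq[i] + seq[i + 1]]
            elif unpaired > MAX_INTERNAL_UNPAIRED:
                return None
            else:
                total += _I10
        else:
            total += _M10
    return total


def dotbracket(n: int, pairs: frozenset) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)


def brute_force_fold(seq: str) -> tuple[float, int, str]:
    """(mfe, n_pairs, structure) by exhaustive enumeration, with the same
    tie-break order as the folder: energy, fewer pairs, lexicographic."""
    best = None
    for pairs in enumerate_structures(seq):
        e = structure_energy10(seq, pairs)
        if e is None:
            continue
        key = (e, len(pairs), dotbracket(len(seq), pairs))
        if best is None or key < best:
            best = key
    assert best is not None  # the empty structure always qualifies
    return best[0] / 10.0, best[1], best[2]


# ---------------------------------------------------------------------------
# Degree correlation (network assortativity), brute force over edges
# ---------------------------------------------------------------------------


def brute_force_degree_correlation(edges) -> float | None:
    """Newman-style endpoint-degree correlation, exact rational arithmetic.

    Each undirected edge contributes both (deg(u), deg(v)) and
    (deg(v), deg(u)). Returns None when the denominator vanishes
    (all endpoint degrees equal)."""
    deg: dict = {}
    for u, v in edges:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    pairs = []
    for u, v in edges:
        pairs.append((deg[u], deg[v]))
        pairs.append((deg[v], deg[u]))
    m = len(pairs)
    if m == 0:
        return None
    mean_jk = Fraction(sum(j * k for j, k in pairs), m)
    mean_half_sum = Fraction(sum(j + k for j, k in pairs), 2 * m)
    mean_half_sq = Fraction(sum(j * j + k * k for j, k in pairs), 2 * m)
    num = mean_jk - mean_half_sum**2
    den = mean_half_sq - mean_half_sum**2
    if den == 0:
        return None
    return float(num / den)


# ---------------------------------------------------------------------------
# Duplex alignment (target-site expectation), brute force over alignments
# ---------------------------------------------------------------------------


def brute_force_duplex(
    mirna: str,
    site: str,
    upsize: int = 20,
    core: tuple[int, int] = (2, 13),
    max_gaps: int = 1,
    penalties=(0.0, 0.5, 1.0, 2.0),  # match, wobble, mismatch, gap
) -> float:
    """Minimal expectation over all global alignments of the miRNA against
    the (already reverse-oriented) site with at most ``max_gaps`` gaps.

    ``site`` here is given 3'->5' relative to the transcript so that
    position p of the miRNA faces position p of the site. Recursive
    enumeration, exponential but fine at oracle lengths (<= 15 nt)."""
    p_match, p_wobble, p_mismatch, p_gap = penalties

    def pair_penalty(m: str, t: str) -> float:
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        if comp.get(m) == t:
            return p_match
        if (m, t) in (("G", "U"), ("U", "G")):
            return p_wobble
        return p_mismatch

    def weight(pos: int, pen: float) -> float:
        # core positions are 1-based on the miRNA, doubled penalties
        return pen * 2 if core[0] <= pos <= core[1] else pen

    best = [float("inf")]

    def rec(mi: int, si: int, gaps: int, acc: float):
        if acc >= best[0]:
            return
        if mi == len(mirna) and si == len(site):
            best[0] = acc
            return
        pos = mi + 1  # next miRNA position, 1-based
        scored = pos <= upsize
        if mi < len(mirna) and si < len(site):
            pen = weight(pos, pair_penalty(mirna[mi], site[si])) if scored else 0.0
            rec(mi + 1, si + 1, gaps, acc + pen)
        if gaps < max_gaps:
            if mi < len(mirna):  # miRNA base faces a gap in the site
                pen = weight(pos, p_gap) if scored else 0.0
                rec(mi + 1, si, gaps + 1, acc + pen)
            if si < len(site):  # site base faces a gap in the miRNA
                pen = weight(pos, p_gap) if scored else 0.0
                rec(mi, si + 1, gaps + 1, acc + pen)
        return

    rec(0, 0, 0, 0.0)
    return best[0]


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(length))
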