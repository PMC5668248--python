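"""Internal RNA secondary-structure folder.

A deliberately compact nearest-neighbor model in the Zuker tradition:

* Watson-Crick (A:U, G:C) and wobble (G:U) pairs; N never pairs.
* Nested structures only (no pseudoknots); hairpin loops >= 3 unpaired.
* Energy = sum of stacking terms for adjacent pairs (16-entry table keyed
  by the 5'-side dinucleotide step) + fixed loop penalties: +3.0 kcal/mol
  per hairpin loop, +2.0 per bulge/internal loop, 0 for multiloops and the
  exterior loop. Bulge/internal loops are capped at 10 unpaired bases in
  total (larger two-loops are simply not formed).
* Ties broken toward fewer pairs, then the lexicographically smaller
  dot-bracket string, so output is fully deterministic.

Energies are carried internally as integers in tenths of kcal/mol so that
tie detection is exact. The model is intentionally coarse: hairpin
discovery needs a stable ranking of stem-loop candidates against a single
free-energy bound, not Turner-accurate values, and an external
thermodynamic folder can be plugged in through :class:`CommandBackend`.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

# Stacking energy (kcal/mol) of two adjacent pairs (i,j) and (i+1,j-1),
# keyed by the 5'-side dinucleotide step seq[i]seq[i+1]. Values follow the
# usual nearest-neighbor ordering: G/C-rich steps stack strongest,
# A/U-only steps weakest.
STACKING_KCAL = {
    "AA": -0.2, "AU": -0.3, "AC": -0.9, "AG": -0.8,
    "UA": -0.3, "UU": -0.2, "UC": -0.8, "UG": -0.6,
    "CA": -0.8, "CU": -0.8, "CC": -1.1, "CG": -1.2,
    "GA": -0.8, "GU": -0.6, "GC": -1.3, "GG": -1.1,
}

HAIRPIN_PENALTY_KCAL = 3.0
INTERNAL_PENALTY_KCAL = 2.0
MULTILOOP_PENALTY_KCAL = 3.0
MIN_HAIRPIN_LOOP = 3
MAX_INTERNAL_UNPAIRED = 10

# Integer tenths for exact arithmetic inside the DP.
_STACK10 = {k: round(v * 10) for k, v in STACKING_KCAL.items()}
_HAIRPIN10 = round(HAIRPIN_PENALTY_KCAL * 10)
_INTERNAL10 = round(INTERNAL_PENALTY_KCAL * 10)
_MULTI10 = round(MULTILOOP_PENALTY_KCAL * 10)

_CAN_PAIR = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})

FIVE_PRIME_ARM = "five_prime_arm"
THREE_PRIME_ARM = "three_prime_arm"
LOOP = "loop"
UNPAIRED_TAIL = "unpaired_tail"


class FoldInputError(ValueError):
    pass


class LoopSpanError(ValueError):
    """A mature span crosses the terminal loop (hairpin-arm criterion broken)."""


@dataclass(frozen=True)
class FoldResult:
    """A nested secondary structure with its minimum free energy."""

    sequence: str
    structure: str
    mfe: float
    pair_table: tuple  # partner index or None, per position

    def __post_init__(self):
        assert len(self.structure) == len(self.sequence)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [
            (i, j) for i, j in enumerate(self.pair_table) if j is not None and i < j
        ]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def can_pair(a: str, b: str) -> bool:
    return a + b in _CAN_PAIR


def parse_dotbracket(structure: str) -> tuple:
    """Dot-bracket -> pair table; raises on unbalanced brackets."""
    table: list[Optional[int]] = [None] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[j], table[i] = i, j
        elif c != ".":
            raise ValueError(f"bad structure character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return tuple(table)


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise FoldInputError(f"sequence contains non-RNA letters: {sorted(bad)}")
    return seq


def fold(sequence: str) -> FoldResult:
    """Minimum free energy nested structure under the built-in model.

    Interval dynamic programme over four tables: ``V`` (best structure
    closed by pair i..j), ``WM1``/``WM2`` (>= 1 / >= 2 helix branches, for
    multiloop interiors) and ``W`` (unconstrained). Each cell stores
    ``(energy, n_pairs, dot_bracket)``; candidates are compared on
    ``(energy, n_pairs)`` first and dot-bracket strings are only
    materialised to break exact ties, which keeps the common path cheap.
    """
    seq = _check_sequence(sequence)
    n = len(seq)
    if n == 0:
        raise FoldInputError("empty sequence")
    if n < MIN_HAIRPIN_LOOP + 2:
        return FoldResult(seq, "." * n, 0.0, (None,) * n)

    NONE = None
    V: list[list] = [[NONE] * n for _ in range(n)]
    WM1: list[list] = [[NONE] * n for _ in range(n)]
    WM2: list[list] = [[NONE] * n for _ in range(n)]
    W: list[list] = [[NONE] * n for _ in range(n)]
    for i in range(n):
        W[i][i] = (0, 0, ".")  # single unpaired base

    def w_get(i: int, j: int):
        if i > j:
            return (0, 0, "")
        return W[i][j]

    def wm1_get(i: int, j: int):
        if i > j:
            return NONE
        return WM1[i][j]

    def wm2_get(i: int, j: int):
        if i > j:
            return NONE
        return WM2[i][j]

    def pick(cands: list) -> Optional[tuple]:
        """cands: list of (e, np, builder). Min by (e, np), ties by string."""
        if not cands:
            return NONE
        best_key = min((e, p) for e, p, _ in cands)
        tied = [c for c in cands if (c[0], c[1]) == best_key]
        if len(tied) == 1:
            e, p, b = tied[0]
            return (e, p, b())
        s = min(b() for _, _, b in tied)
        return (best_key[0], best_key[1], s)

    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span

            # ---- V: best structure with (i, j) paired -------------------
            if span >= MIN_HAIRPIN_LOOP + 1 and can_pair(seq[i], seq[j]):
                cands = [
                    (_HAIRPIN10, 1, (lambda i=i, j=j: "(" + "." * (j - i - 1) + ")"))
                ]
                # two-loop: exactly one inner pair (k, l)
                for k in range(i + 1, j - MIN_HAIRPIN_LOOP - 1):
                    up5 = k - i - 1
                    if up5 > MAX_INTERNAL_UNPAIRED:
                        break
                    row = V[k]
                    for l in range(j - 1, k + MIN_HAIRPIN_LOOP, -1):
                        up3 = j - l - 1
                        if up5 + up3 > MAX_INTERNAL_UNPAIRED:
                            break
                        inner = row[l]
                        if inner is NONE:
                            continue
                        if up5 == 0 and up3 == 0:
                            cost = _STACK10[seq[i] + seq[i + 1]]
                        else:
                            cost = _INTERNAL10
                        cands.append(
                            (
                                inner[0] + cost,
                                inner[1] + 1,
                                (
                                    lambda s=inner[2], u5=up5, u3=up3: "("
                                    + "." * u5
                                    + s
                                    + "." * u3
                                    + ")"
                                ),
                            )
                        )
                # multiloop: >= 2 branches inside
                multi = wm2_get(i + 1, j - 1)
                if multi is not NONE:
                    cands.append(
                        (
                            multi[0] + _MULTI10,
                            multi[1] + 1,
                            (lambda s=multi[2]: "(" + s + ")"),
                        )
                    )
                V[i][j] = pick(cands)

            # ---- WM1 / WM2 / W ------------------------------------------
            wm1_c, wm2_c = [], []
            w_c = [(0, 0, (lambda m=span + 1: "." * m))]
            sub = wm1_get(i + 1, j)
            if sub is not NONE:
                wm1_c.append((sub[0], sub[1], (lambda s=sub[2]: "." + s)))
            sub2 = wm2_get(i + 1, j)
            if sub2 is not NONE:
                wm2_c.append((sub2[0], sub2[1], (lambda s=sub2[2]: "." + s)))
            subw = w_get(i + 1, j)
            w_c.append((subw[0], subw[1], (lambda s=subw[2]: "." + s)))
            for l in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                first = V[i][l]
                if first is NONE:
                    continue
                rest_w = w_get(l + 1, j)
                wm1_c.append(
                    (
                        first[0] + rest_w[0],
                        first[1] + rest_w[1],
                        (lambda a=first[2], b=rest_w[2]: a + b),
                    )
                )
                w_c.append(
                    (
                        first[0] + rest_w[0],
                        first[1] + rest_w[1],
                        (lambda a=first[2], b=rest_w[2]: a + b),
                    )
                )
                rest_m = wm1_get(l + 1, j)
                if rest_m is not NONE:
                    wm2_c.append(
                        (
                            first[0] + rest_m[0],
                            first[1] + rest_m[1],
                            (lambda a=first[2], b=rest_m[2]: a + b),
                        )
                    )
            WM1[i][j] = pick(wm1_c)
            WM2[i][j] = pick(wm2_c)
            W[i][j] = pick(w_c)

    e10, _, structure = W[0][n - 1]
    return FoldResult(seq, structure, e10 / 10.0, parse_dotbracket(structure))


# ---------------------------------------------------------------------------
# Hairpin anatomy
# ---------------------------------------------------------------------------


def _stem_paths(result: FoldResult) -> list[dict]:
    """One record per hairpin: its closing pair, outermost stem pair, and
    the number of pairs along the (internal-loop-tolerant) stem path."""
    pt = result.pair_table
    pairs = result.pairs
    if not pairs:
        return []
    pair_set = dict(pairs)  # i -> j for i < j
    # children: pairs directly nested inside a pair
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    roots = []
    # enclosing pair of each pair, via nesting scan
    stack: list[tuple[int, int]] = []
    for i in range(len(pt)):
        if pt[i] is not None and i < pt[i]:
            p = (i, pt[i])
            while stack and stack[-1][1] < i:
                stack.pop()
            if stack:
                children[stack[-1]].append(p)
            else:
                roots.append(p)
            stack.append(p)
        elif pt[i] is not None and i > pt[i]:
            while stack and stack[-1][1] <= i:
                stack.pop()
    parent = {}
    for p, kids in children.items():
        for k in kids:
            parent[k] = p
    stems = []
    for p in pairs:
        if children[(p[0], p[1])]:
            continue  # not a hairpin-closing pair
        hairpin = p
        top = p
        count = 1
        while top in parent and len(children[parent[top]]) == 1:
            top = parent[top]
            count += 1
        stems.append(
            {"hairpin": hairpin, "outer": top, "n_pairs": count}
        )
    return stems


def maximal_stem(result: FoldResult) -> Optional[dict]:
    """The stem with the most pairs along its hairpin path (ties: leftmost)."""
    stems = _stem_paths(result)
    if not stems:
        return None
    return min(stems, key=lambda s: (-s["n_pairs"], s["hairpin"][0]))


def arm_of(position: int, result: FoldResult) -> str:
    """Classify a position relative to the maximal stem's terminal loop."""
    if position < 0 or position >= len(result.sequence):
        raise IndexError(f"position {position} outside sequence")
    stem = maximal_stem(result)
    if stem is None:
        return UNPAIRED_TAIL
    h5, h3 = stem["hairpin"]
    o5, o3 = stem["outer"]
    if h5 < position < h3:
        return LOOP
    if o5 <= position <= h5:
        return FIVE_PRIME_ARM
    if h3 <= position <= o3:
        return THREE_PRIME_ARM
    return UNPAIRED_TAIL


def duplex_mismatches(mature_span: tuple[int, int], result: FoldResult) -> int:
    """Mature positions unpaired or paired outside the opposite arm.

    ``mature_span`` is 0-based half-open. Raises :class:`LoopSpanError`
    when the span has bases in the terminal loop or on both arms, which is
    a violation of the one-arm criterion rather than a mismatch count.
    """
    start, end = mature_span
    if not (0 <= start < end <= len(result.sequence)):
        raise IndexError(f"span {mature_span} outside sequence")
    stem = maximal_stem(result)
    if stem is None:
        return end - start
    arms = [arm_of(p, result) for p in range(start, end)]
    if LOOP in arms:
        raise LoopSpanError("mature span crosses the terminal loop")
    present = {a for a in arms if a in (FIVE_PRIME_ARM, THREE_PRIME_ARM)}
    if len(present) > 1:
        raise LoopSpanError("mature span covers both arms of the hairpin")
    h5, h3 = stem["hairpin"]
    o5, o3 = stem["outer"]
    if present == {THREE_PRIME_ARM}:
        opposite = range(o5, h5 + 1)
    else:
        opposite = range(h3, o3 + 1)
    count = 0
    for p in range(start, end):
        partner = result.pair_table[p]
        if partner is None or partner not in opposite:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Pluggable backend
# ---------------------------------------------------------------------------

FoldBackend = Callable[[str], FoldResult]


class CommandBackend:
    """External folder via a shell command (ViennaRNA-style contract).

    The command receives the sequence on stdin and must print at least one
    line containing a dot-bracket string followed by an energy in
    parentheses, e.g. ``((((...)))) ( -4.20)``. ``RNAfold --noPS`` fits.
    """

    def __init__(self, command: str):
        self.command = command

    def __call__(self, sequence: str) -> FoldResult:
        seq = _check_sequence(sequence)
        out = subprocess.run(
            shlex.split(self.command),
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout
        for line in out.splitlines():
            token = line.strip().split(" ")[0]
            if token and set(token) <= set("().") and len(token) == len(seq):
                energy = float(
                    line[line.rindex("(") + 1 : line.rindex(")")].strip()
                )
                return FoldResult(seq, token, energy, parse_dotbracket(token))
        raise ValueError(
            f"backend output contains no dot-bracket line for {self.command!r}"
        )


def get_backend(name: str = "builtin", command: str | None = None) -> FoldBackend:
    if name == "builtin":
        return fold
    if name == "command":
        if not command:
            raise ValueError("fold.backend=command requires a command template")
        return CommandBackend(command)
    raise ValueError(f"unknown fold backend {name!r}")
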