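"""Hairpin folding and miRNA:miRNA* duplex statistics.

Folding is base-pair maximization (a Nussinov-style dynamic program) over
Watson-Crick pairs plus the G:U wobble (G:T in the internal DNA alphabet),
with a minimum hairpin-loop length of 3 and N positions forced unpaired.
The pipeline's criteria consume only pairing topology, so maximizing pairs
gives a deterministic, independently checkable stand-in for free-energy
folding; an externally supplied dot-bracket can override it per candidate.

Pair-count maximization alone is highly degenerate: a random window admits
many co-optimal structures, and count-neutral "partner stealing" swaps can
scramble even a perfect stem.  The objective is therefore lexicographic —
maximize the number of pairs first, then the number of stacked pairs
(helix continuations) — implemented as an integer score of 1000 per pair
plus 1 per stack (the stacking total can never trade against a pair at the
window sizes folded here).  Remaining ties resolve deterministically: a
base pairs only when strictly required for the optimum, then with its
farthest co-optimal partner, preferring continued helices inward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import normalize_sequence

MIN_LOOP = 3

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# allowed pairs: A:T, G:C and the G:T wobble; N never pairs
_PAIR_OK = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in [(0, 3), (2, 1), (2, 3)]:
    _PAIR_OK[_a, _b] = True
    _PAIR_OK[_b, _a] = True


PAIR_SCORE = 1000  # lexicographic weight: pairs dominate stacking bonuses
_NEG = -(1 << 30)


def _fill_python(codes: np.ndarray, min_loop: int) -> tuple[np.ndarray, np.ndarray]:
    """Fill W (best score of [i..j]) and V (best given i pairs j)."""
    n = len(codes)
    W = np.zeros((n, n), dtype=np.int64)
    V = np.full((n, n), _NEG, dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if _PAIR_OK[codes[i], codes[j]]:
                inner = W[i + 1, j - 1]
                if V[i + 1, j - 1] > _NEG and V[i + 1, j - 1] + 1 > inner:
                    inner = V[i + 1, j - 1] + 1  # stacked helix continuation
                V[i, j] = PAIR_SCORE + inner
            best = W[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if V[i, k] > _NEG:
                    cand = V[i, k] + (W[k + 1, j] if k + 1 <= j else 0)
                    if cand > best:
                        best = cand
            W[i, j] = best
    return W, V


try:  # numba accelerates the O(n^3) fill; the pure fill is the fallback
    import numba

    @numba.njit(cache=True)
    def _fill_numba(codes, min_loop, pair_ok):  # pragma: no cover - jitted
        n = len(codes)
        W = np.zeros((n, n), dtype=np.int64)
        V = np.full((n, n), _NEG, dtype=np.int64)
        for span in range(min_loop + 1, n):
            for i in range(0, n - span):
                j = i + span
                if pair_ok[codes[i], codes[j]]:
                    inner = W[i + 1, j - 1]
                    if V[i + 1, j - 1] > _NEG and V[i + 1, j - 1] + 1 > inner:
                        inner = V[i + 1, j - 1] + 1
                    V[i, j] = PAIR_SCORE + inner
                best = W[i + 1, j]
                for k in range(i + min_loop + 1, j + 1):
                    if V[i, k] > _NEG:
                        rest = W[k + 1, j] if k + 1 <= j else 0
                        cand = V[i, k] + rest
                        if cand > best:
                            best = cand
                W[i, j] = best
        return W, V

    def _fill(codes: np.ndarray, min_loop: int) -> tuple[np.ndarray, np.ndarray]:
        return _fill_numba(codes, min_loop, _PAIR_OK)

except Exception:  # pragma: no cover
    _fill = _fill_python


class NoStarError(ValueError):
    """The miRNA placement admits no miRNA* (e.g. it spans the terminal loop)."""


@dataclass
class HairpinStructure:
    """A sequence with its non-crossing pairing (dot-bracket + partner table)."""

    sequence: str
    dotbracket: str
    pair_map: list[int]  # partner index per position, -1 when unpaired

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.dotbracket) == len(self.pair_map)):
            raise ValueError("structure fields must have equal length")

    @property
    def n_pairs(self) -> int:
        return sum(1 for p in self.pair_map if p >= 0) // 2


def pairmap_from_dotbracket(db: str) -> list[int]:
    pair_map = [-1] * len(db)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pair_map[i], pair_map[j] = j, i
        elif c != ".":
            raise ValueError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pair_map


def dotbracket_from_pairmap(pair_map: Sequence[int]) -> str:
    return "".join(
        "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(pair_map)
    )


def structure_from_dotbracket(sequence: str, dotbracket: str) -> HairpinStructure:
    """Build a structure from an external dot-bracket (per-candidate override)."""
    seq = normalize_sequence(sequence)
    return HairpinStructure(seq, dotbracket, pairmap_from_dotbracket(dotbracket))


def fold_hairpin(seq: str, min_loop: int = MIN_LOOP) -> HairpinStructure:
    """Maximum-base-pair non-crossing structure of ``seq`` (deterministic)."""
    s = normalize_sequence(seq)
    codes = np.array([_CODE[c] for c in s], dtype=np.int8)
    n = len(codes)
    pair_map = [-1] * n
    if n > min_loop + 1:
        W, V = _fill(codes, min_loop)

        def trace_v(i: int, j: int) -> None:
            # region [i..j] with i paired to j
            while True:
                pair_map[i], pair_map[j] = j, i
                target = V[i, j] - PAIR_SCORE
                if (
                    j - 1 - (i + 1) > min_loop
                    and V[i + 1, j - 1] > _NEG
                    and V[i + 1, j - 1] + 1 == target
                ):
                    i, j = i + 1, j - 1  # continue the helix inward
                    continue
                trace_w(i + 1, j - 1)
                return

        def trace_w(i: int, j: int) -> None:
            while i < j:
                target = W[i, j]
                if target == 0:
                    return
                if W[i + 1, j] == target:
                    i += 1  # pairing i is not required for the optimum
                    continue
                for k in range(j, i + min_loop, -1):
                    if V[i, k] > _NEG:
                        rest = W[k + 1, j] if k + 1 <= j else 0
                        if V[i, k] + rest == target:
                            trace_v(i, k)
                            i = k + 1
                            break
                else:  # pragma: no cover - unreachable if W/V are consistent
                    i += 1

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 2 * n + 100))
        try:
            trace_w(0, n - 1)
        finally:
            sys.setrecursionlimit(old)
    return HairpinStructure(s, dotbracket_from_pairmap(pair_map), pair_map)


# ---------------------------------------------------------------------------
# miRNA* localization
# ---------------------------------------------------------------------------


def locate_star(
    structure: HairpinStructure,
    mir_start: int,
    mir_len: int,
    min_paired: int | None = None,
) -> tuple[int, int]:
    """Locate the miRNA* interval implied by the miRNA placement.

    The star spans the partners of the miRNA's paired bases, extended to give
    the canonical 2-nt 3' overhang on both duplex ends.  Raises
    :class:`NoStarError` when the miRNA spans the terminal loop or is mostly
    unpaired (fewer than ``min_paired`` bases paired; default
    ``mir_len - 4``, relaxed by callers that tolerate more duplex defects).
    """
    m0, m1 = mir_start, mir_start + mir_len
    if m0 < 0 or m1 > len(structure.sequence):
        raise ValueError("miRNA interval outside structure")
    if min_paired is None:
        min_paired = mir_len - 4
    paired = [i for i in range(m0, m1) if structure.pair_map[i] >= 0]
    if len(paired) < min_paired:
        raise NoStarError("miRNA mostly unpaired in the structure")
    partners = [structure.pair_map[i] for i in paired]
    if any(m0 <= p < m1 for p in partners):
        raise NoStarError("miRNA pairs with itself (spans the terminal loop)")
    below = any(p < m0 for p in partners)
    above = any(p >= m1 for p in partners)
    if below and above:
        raise NoStarError("miRNA partners on both sides (crosses the loop midpoint)")

    p_first = paired[0]  # 5'-most paired miRNA base; its partner caps the star 3' end
    j_hi = structure.pair_map[p_first]
    anchor = m1 - 3  # last base of the miRNA's duplex region (2-nt 3' overhang)
    cands = [i for i in paired if i <= anchor]
    p_last = cands[-1] if cands else paired[-1]
    j_lo = structure.pair_map[p_last]
    star_start = j_lo
    star_end = min(j_hi + 3, len(structure.sequence))
    if star_start >= star_end:
        raise NoStarError("degenerate star interval")
    if not (star_end <= m0 or star_start >= m1):
        raise NoStarError("star interval overlaps the miRNA")
    return star_start, star_end - star_start


# ---------------------------------------------------------------------------
# duplex statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplexStats:
    """Defect counts of a miRNA:miRNA* duplex.

    Opposed unpaired runs count min(len, len) mismatches (one per opposed
    position pair); the unopposed remainder of an asymmetric run counts as a
    single bulge whose length is recorded.
    """

    mismatches: int
    bulges: int
    max_bulge_len: int

    @property
    def total_defects(self) -> int:
        return self.mismatches + self.bulges


def duplex_stats(
    structure: HairpinStructure,
    mir_interval: tuple[int, int],
    star_interval: tuple[int, int],
) -> DuplexStats:
    """Count mismatches and bulges between the two duplex arms.

    Each strand's 2-nt 3' overhang (the last two positions of its interval)
    is outside the duplex and ignored.  The computation is symmetric in its
    two interval arguments.
    """
    m0, m1 = mir_interval
    s0, s1 = star_interval
    md_lo, md_hi = m0, max(m0, m1 - 2)  # duplex region of each strand
    sd_lo, sd_hi = s0, max(s0, s1 - 2)

    pairs = []
    for i in range(md_lo, md_hi):
        j = structure.pair_map[i]
        if sd_lo <= j < sd_hi:
            pairs.append((i, j))
    # keep a strictly antiparallel chain (partners must descend)
    chain: list[tuple[int, int]] = []
    for i, j in pairs:
        if not chain or j < chain[-1][1]:
            chain.append((i, j))

    mism = 0
    bulges = 0
    max_bulge = 0

    def gap(gm: int, gs: int) -> None:
        nonlocal mism, bulges, max_bulge
        mism += min(gm, gs)
        diff = abs(gm - gs)
        if diff > 0:
            bulges += 1
            max_bulge = max(max_bulge, diff)

    if not chain:
        gap(md_hi - md_lo, sd_hi - sd_lo)
        return DuplexStats(mism, bulges, max_bulge)

    prev_i, prev_j = md_lo - 1, sd_hi
    for i, j in chain:
        gap(i - prev_i - 1, prev_j - j - 1)
        prev_i, prev_j = i, j
    gap(md_hi - prev_i - 1, prev_j - sd_lo)
    return DuplexStats(mism, bulges, max_bulge)


# ---------------------------------------------------------------------------
# locus bias statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusTag:
    """A tag mapped within a candidate precursor locus."""

    tag: str
    start: int  # 0-based offset within the locus / genome
    strand: str  # '+' = precursor (sense) strand
    abundance: float


def strand_bias(locus_tags: Iterable[LocusTag], sense: str = "+") -> float:
    """Sense-strand share of total locus abundance (in [0, 1])."""
    tags = list(locus_tags)
    total = sum(t.abundance for t in tags)
    if total <= 0:
        raise ValueError("strand bias undefined: zero total abundance")
    return sum(t.abundance for t in tags if t.strand == sense) / total


def abundance_bias(locus_tags: Iterable[LocusTag]) -> float:
    """Share of locus abundance carried by its top two tags.

    Ties in "top two" are broken by 5'-most start, then lexicographic tag
    (the value is tie-invariant; the rule fixes which tags are reported).
    """
    tags = sorted(locus_tags, key=lambda t: (-t.abundance, t.start, t.tag))
    if not tags:
        raise ValueError("abundance bias undefined: no tags")
    total = sum(t.abundance for t in tags)
    if total <= 0:
        raise ValueError("abundance bias undefined: zero total abundance")
    return sum(t.abundance for t in tags[:2]) / total
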