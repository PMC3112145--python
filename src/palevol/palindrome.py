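"""Dot-matrix self-comparison and inverted-repeat (palindrome) detection.

Large genomic palindromes are pairs of high-identity inverted-repeat "arms"
flanking a unique "loop" spacer.  Detection here is seed-and-chain: exact
k-word matches of the sequence against itself (forward and reverse
complement) are chained along diagonals into ungapped segments, inverted
segments are merged into arm pairs, and arm identity is computed from a
global edit-distance alignment of the two arm spans.  Similarity fractions
are binned into the four color classes used for dot-plot display, and
duplicated units can be matched across species by shared transposable-
element insertion markers (near-homoplasy-free cladistic characters).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from palevol.errors import ParameterError
from palevol.seqmodel import Interval, NucSequence, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class MatchSegment:
    """An ungapped matched segment pair from self-comparison."""

    query: Interval
    subject: Interval
    orientation: str  # "direct" | "inverted"
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ParameterError(f"identity {self.identity} outside [0, 1]")
        if self.orientation not in ("direct", "inverted"):
            raise ParameterError(f"orientation must be direct/inverted, got {self.orientation!r}")


@dataclass
class PalindromeCall:
    """A predicted palindrome: two inverted arms around a loop spacer."""

    arm1: Interval
    arm2: Interval
    loop: Optional[Interval]
    arm_identity: float
    arm_length: int
    center: int


@dataclass
class DuplicatedUnit:
    """A duplicated repeat unit with its contained cladistic markers."""

    interval: Interval
    label: str
    markers: frozenset = frozenset()


# ---------------------------------------------------------------------------
# Self comparison

def _chain_hits(hit_positions: list[int], k: int, max_gap: int) -> list[tuple[int, int]]:
    """Chain sorted k-mer hit start positions into runs; return (start, end) spans."""
    runs = []
    start = prev = hit_positions[0]
    for p in hit_positions[1:]:
        if p - prev > max_gap:
            runs.append((start, prev + k))
            start = p
        prev = p
    runs.append((start, prev + k))
    return runs


def _ungapped_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return matches / n


def self_compare(
    seq: NucSequence,
    k: int = 12,
    min_segment: int = 300,
    max_gap: Optional[int] = None,
) -> list[MatchSegment]:
    """Dot-matrix style self-comparison by exact k-word seeding and chaining.

    Seeds are exact k-mer matches of the sequence against itself on the
    forward strand (direct repeats) and against its reverse complement
    (inverted repeats).  Seeds on a common (anti)diagonal separated by at
    most ``max_gap`` (default ``2k``) are chained; chains shorter than
    ``min_segment`` are dropped.  The trivial self-diagonal is excluded and
    each off-diagonal match is reported once (query before subject).
    Identity is computed on the gap-free chained extension.
    """
    if k < 8:
        raise ParameterError("word size k must be >= 8")
    s = seq.residues
    L = len(s)
    if L < 2 * k:
        raise ParameterError("sequence shorter than 2k")
    if max_gap is None:
        max_gap = 2 * k

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(L - k + 1):
        word = s[i : i + k]
        if "N" not in word:
            index[word].append(i)

    # direct matches: pairs (i, j), i < j, grouped by diagonal j - i
    direct: dict[int, list[int]] = defaultdict(list)
    for word, positions in index.items():
        if len(positions) > 1:
            for ai in range(len(positions)):
                for bi in range(ai + 1, len(positions)):
                    i, j = positions[ai], positions[bi]
                    direct[j - i].append(i)

    # inverted matches: k-mer at i equals revcomp of k-mer at j; constant i+j.
    # each unordered occurrence pair is recorded once at its left (query)
    # position min(i, j)
    inverted: dict[int, list[int]] = defaultdict(list)
    for word, positions in index.items():
        rc = reverse_complement(word)
        if rc < word:
            continue  # visit each complementary word pair once
        rpos = index.get(rc)
        if not rpos:
            continue
        for i in positions:
            for j in rpos:
                if word == rc and j <= i:
                    continue  # palindromic word: avoid double count / self hit
                inverted[i + j].append(min(i, j))

    segments: list[MatchSegment] = []
    for diag, hits in direct.items():
        hits = sorted(set(hits))
        for q0, q1 in _chain_hits(hits, k, max_gap):
            if q1 - q0 < min_segment:
                continue
            s0, s1 = q0 + diag, q1 + diag
            ident = _ungapped_identity(s[q0:q1], s[s0:s1])
            segments.append(
                MatchSegment(
                    Interval(seq.id, q0, q1, "+"),
                    Interval(seq.id, s0, s1, "+"),
                    "direct",
                    ident,
                )
            )
    for anti, hits in inverted.items():
        hits = sorted(set(hits))
        for q0, q1 in _chain_hits(hits, k, max_gap):
            if q1 - q0 < min_segment:
                continue
            # query k-mer start i pairs with subject k-mer start anti - i
            s0, s1 = anti - (q1 - k), anti - q0 + k
            if s0 < 0 or s1 > L:
                continue
            ident = _ungapped_identity(s[q0:q1], reverse_complement(s[s0:s1]))
            segments.append(
                MatchSegment(
                    Interval(seq.id, q0, q1, "+"),
                    Interval(seq.id, s0, s1, "-"),
                    "inverted",
                    ident,
                )
            )
    segments.sort(key=lambda m: (m.query.start, m.subject.start))
    logger.info("self_compare(%s): %d segments", seq.id, len(segments))
    return segments


def bin_similarity(identity: float) -> str:
    """GenomeMatcher-style similarity color class.

    ``> 0.95`` red; ``(0.90, 0.95]`` orange; ``(0.85, 0.90]`` green;
    ``<= 0.85`` blue (half-open convention at the stated boundaries).
    """
    if not 0.0 <= identity <= 1.0:
        raise ParameterError(f"identity {identity} outside [0, 1]")
    if identity > 0.95:
        return "red"
    if identity > 0.90:
        return "orange"
    if identity > 0.85:
        return "green"
    return "blue"


# ---------------------------------------------------------------------------
# Palindrome calls

def _arm_identity(seq: str, arm1: Interval, arm2: Interval) -> float:
    """Identity of arm1 vs reverse complement of arm2 by global edit distance."""
    a = seq[arm1.start : arm1.end]
    b = reverse_complement(seq[arm2.start : arm2.end])
    res = edlib.align(a, b, mode="NW", task="distance")
    aln_len = max(len(a), len(b))
    return 1.0 - res["editDistance"] / aln_len


def _polish_pair(s: str, a: int, b: int, step_a: int, step_b: int,
                 block: int = 16, min_matches: int = 10,
                 max_extension: Optional[int] = None) -> tuple[int, int]:
    """Extend an (arm1, arm2) boundary pair outward in mirrored blocks.

    Compares ``block``-sized windows of arm1 sequence against the reverse
    complement of the mirrored arm2 window, advancing while at least
    ``min_matches`` positions agree.  This recovers arm ends that exact
    k-word chains fall short of when arm divergence is high; it assumes no
    indel within the extension, so it simply stops at structural breaks.
    """
    L = len(s)
    extended = 0
    while max_extension is None or extended + block <= max_extension:
        if step_a < 0:
            na0, na1 = a + step_a * block, a
        else:
            na0, na1 = a, a + step_a * block
        if step_b < 0:
            nb0, nb1 = b + step_b * block, b
        else:
            nb0, nb1 = b, b + step_b * block
        if na0 < 0 or nb0 < 0 or na1 > L or nb1 > L:
            return a, b
        wa = s[na0:na1]
        wb = reverse_complement(s[nb0:nb1])
        if sum(1 for x, y in zip(wa, wb) if x == y) < min_matches:
            return a, b
        a += step_a * block
        b += step_b * block
        extended += block
    return a, b


def detect_palindromes(
    segments: Sequence[MatchSegment],
    seq: NucSequence,
    min_arm: int = 1000,
    min_identity: float = 0.90,
    merge_gap: int = 5000,
) -> list[PalindromeCall]:
    """Merge inverted match segments into palindrome calls.

    Inverted segments whose query/subject spans are close (within
    ``merge_gap``) and mirror-ordered are clustered into one arm pair; the
    loop is the gap between the merged arms.  Arm identity is recomputed
    from a global edit-distance alignment of the full arm spans.
    Overlapping calls are resolved longest-arm-first.
    """
    inv = [m for m in segments if m.orientation == "inverted" and not m.query.overlaps(m.subject)]
    if not inv:
        return []
    inv = sorted(inv, key=lambda m: m.query.start)
    clusters: list[list[MatchSegment]] = []
    for m in inv:
        placed = False
        for cl in clusters:
            q_end = max(x.query.end for x in cl)
            s_lo = min(x.subject.start for x in cl)
            s_hi = max(x.subject.end for x in cl)
            if (
                m.query.start <= q_end + merge_gap
                and s_lo - merge_gap <= m.subject.end
                and m.subject.start <= s_hi + merge_gap
                and m.query.end <= m.subject.start  # arms stay disjoint
            ):
                cl.append(m)
                placed = True
                break
        if not placed:
            clusters.append([m])

    calls: list[PalindromeCall] = []
    s = seq.residues
    for cl in clusters:
        a0 = min(x.query.start for x in cl)
        a1 = max(x.query.end for x in cl)
        b0 = min(x.subject.start for x in cl)
        b1 = max(x.subject.end for x in cl)
        if a1 > b0:  # arms overlap: trim at midpoint
            mid = (a1 + b0) // 2
            a1, b0 = mid, mid
        # polish boundaries beyond the outermost exact-word chains
        a0, b1 = _polish_pair(s, a0, b1, -1, +1)
        a1, b0 = _polish_pair(s, a1, b0, +1, -1, max_extension=max(0, (b0 - a1) // 2 - 16))
        if a1 - a0 < min_arm or b1 - b0 < min_arm:
            continue
        arm1 = Interval(seq.id, a0, a1, "+", "arm1")
        arm2 = Interval(seq.id, b0, b1, "-", "arm2")
        loop = Interval(seq.id, a1, b0, "+", "loop") if b0 > a1 else None
        ident = _arm_identity(seq.residues, arm1, arm2)
        if ident < min_identity:
            continue
        center = (a1 + b0) // 2
        calls.append(
            PalindromeCall(
                arm1=arm1,
                arm2=arm2,
                loop=loop,
                arm_identity=ident,
                arm_length=(len(arm1) + len(arm2)) // 2,
                center=center,
            )
        )

    calls.sort(key=lambda c: c.arm_length, reverse=True)
    kept: list[PalindromeCall] = []
    for c in calls:
        span = Interval(seq.id, c.arm1.start, c.arm2.end)
        if any(span.overlaps(Interval(seq.id, k.arm1.start, k.arm2.end)) for k in kept):
            continue
        kept.append(c)
    logger.info("detect_palindromes(%s): %d calls", seq.id, len(kept))
    return kept


# ---------------------------------------------------------------------------
# Unit orthology by shared cladistic markers

@dataclass
class OrthologyAssignment:
    scores: np.ndarray            # |units_a| x |units_b| Jaccard matrix
    pairs: list[tuple[str, str, float]]
    unassigned_a: list[str]
    unassigned_b: list[str]
    flagged_empty: list[str]


def unit_orthology_scores(
    units_a: Sequence[DuplicatedUnit], units_b: Sequence[DuplicatedUnit]
) -> OrthologyAssignment:
    """Score unit orthology by the Jaccard index of shared marker sets.

    Shared transposable-element insertions are near-homoplasy-free, so a
    high Jaccard overlap of marker labels identifies orthologous duplicated
    units across species.  Assignment is greedy one-to-one by descending
    score; ties are broken by positional order.  Units with empty marker
    sets score 0 against everything and are flagged.
    """
    na, nb = len(units_a), len(units_b)
    scores = np.zeros((na, nb))
    for i, ua in enumerate(units_a):
        for j, ub in enumerate(units_b):
            union = ua.markers | ub.markers
            scores[i, j] = len(ua.markers & ub.markers) / len(union) if union else 0.0
    order = sorted(
        ((i, j) for i in range(na) for j in range(nb)),
        key=lambda ij: (-scores[ij], ij[0], ij[1]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for i, j in order:
        if scores[i, j] <= 0.0:
            break
        if i in used_a or j in used_b:
            continue
        pairs.append((units_a[i].label, units_b[j].label, float(scores[i, j])))
        used_a.add(i)
        used_b.add(j)
    flagged = [u.label for u in list(units_a) + list(units_b) if not u.markers]
    return OrthologyAssignment(
        scores=scores,
        pairs=pairs,
        unassigned_a=[u.label for i, u in enumerate(units_a) if i not in used_a],
        unassigned_b=[u.label for j, u in enumerate(units_b) if j not in used_b],
        flagged_empty=flagged,
    )
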