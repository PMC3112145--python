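"""Gene-conversion detection via Sawyer's fragment statistic.

For each pair of sequences in a multiple alignment, informative
(polymorphic, ungapped) sites are scored +1 where the pair agrees and
``-(g+1)`` where it disagrees; maximal-scoring runs (fragments) that are
unusually long given the pair's overall mismatch rate indicate tracts
homogenized by gene conversion.  Significance is assessed by permuting the
site order (Sawyer's null: site independence), and p-values are
Bonferroni-corrected across sequence pairs.  Only inner fragments
(pairwise within the alignment) are considered.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from palevol.errors import NoDataError, ParameterError
from palevol.palindrome import DuplicatedUnit

logger = logging.getLogger(__name__)

_BASES = frozenset(b"ACGT")


@dataclass
class PolymorphicSiteTable:
    """Informative-site matrix: polymorphic, ungapped columns only."""

    ids: list[str]
    positions: np.ndarray          # original alignment columns of retained sites
    alleles: np.ndarray            # (n_seqs, n_sites) byte array

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def build_site_table(aln: dict[str, str] | Sequence[tuple[str, str]]) -> PolymorphicSiteTable:
    """Reduce a multiple alignment to its polymorphic, ungapped columns.

    Columns containing a gap or ``N`` in any sequence are excluded; retained
    columns keep their original alignment coordinates.  Needs >= 3
    sequences (inner fragments are defined by an "others differ" context)
    and >= 2 polymorphic sites.
    """
    items = list(aln.items()) if isinstance(aln, dict) else list(aln)
    if len(items) < 3:
        raise ParameterError("site table needs >= 3 sequences")
    ids = [i for i, _ in items]
    rows = [s.upper() for _, s in items]
    if len({len(r) for r in rows}) != 1:
        raise ParameterError("aligned sequences have unequal lengths")
    arr = np.array([np.frombuffer(r.encode(), dtype="S1") for r in rows])
    valid = np.isin(arr, np.array(list("ACGT"), dtype="S1")).all(axis=0)
    poly = (arr != arr[0]).any(axis=0)
    keep = valid & poly
    if keep.sum() < 2:
        raise NoDataError("fewer than 2 polymorphic ungapped sites")
    return PolymorphicSiteTable(ids, np.flatnonzero(keep), arr[:, keep])


@dataclass
class ConversionFragment:
    """A candidate gene-conversion tract between one sequence pair."""

    id_a: str
    id_b: str
    start_site: int     # index into the site table
    end_site: int       # inclusive
    start_bp: int       # alignment column of first site
    end_bp: int         # alignment column of last site (inclusive)
    n_sites: int
    score: float
    sim_p: float        # per-pair permutation p-value
    p_adjusted: float   # Bonferroni across pairs
    listing: str = "inner"


def _max_segments(scores: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal positive-scoring segments (Ruzzo-Tompa, linear time).

    Returns (start, end_exclusive, score) sorted by descending score.
    """
    # stack entries: [start, end, L_cum, R_cum] where L/R are cumulative
    # scores just before the segment and at its end (Ruzzo & Tompa 1999)
    stack: list[list] = []
    cum = 0.0
    for i, x in enumerate(scores):
        prev_cum = cum
        cum += x
        if x <= 0.0:
            continue
        cur = [i, i + 1, prev_cum, cum]
        while True:
            # find rightmost stacked segment j with L_j < L_cur
            merged = False
            for j in range(len(stack) - 1, -1, -1):
                if stack[j][2] < cur[2]:
                    if stack[j][3] >= cur[3]:
                        break  # step 1 fails: just push
                    # merge j..top and current into one segment
                    cur = [stack[j][0], cur[1], stack[j][2], cur[3]]
                    del stack[j:]
                    merged = True
                    break
            if not merged:
                stack.append(cur)
                break
    segs = []
    for s0, s1, lcum, rcum in stack:
        while s1 > s0 and scores[s1 - 1] <= 0:
            s1 -= 1
        segs.append((s0, s1, float(rcum - lcum)))
    segs.sort(key=lambda t: -t[2])
    return segs


def _null_max_scores(score_vec: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Maximal segment score of ``n_perm`` site-order permutations (vectorized)."""
    n = len(score_vec)
    mat = np.tile(score_vec, (n_perm, 1))
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    mat = np.take_along_axis(mat, idx, axis=1)
    S = np.cumsum(mat, axis=1)
    prefix = np.minimum.accumulate(np.hstack([np.zeros((n_perm, 1)), S])[:, :-1], axis=1)
    return (S - prefix).max(axis=1)


def sawyer_fragments(
    table: PolymorphicSiteTable,
    g: float = 1.0,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    report_all: bool = False,
) -> list[ConversionFragment]:
    """Sawyer fragment statistic with permutation significance.

    Per sequence pair, informative sites score +1 (agree) or ``-(g+1)``
    (disagree); the maximal-scoring fragment and further disjoint maximal
    fragments are extracted.  For each pair, ``n_permutations`` site-order
    shuffles give the null distribution of the maximal score, and the
    fragment p-value is the fraction of shuffles reaching its score
    (add-one estimator).  P-values are Bonferroni-multiplied by the number
    of pairs tested; fragments with adjusted p <= ``alpha`` are returned
    (all fragments with ``report_all``).  Pairs with no disagreeing site
    carry no informative contrast and are skipped.
    """
    if g < 0:
        raise ParameterError("mismatch penalty g must be >= 0")
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    n_seq = len(table.ids)
    pairs = list(itertools.combinations(range(n_seq), 2))
    out: list[ConversionFragment] = []
    n_tested = 0
    results = []
    for a, b in pairs:
        agree = table.alleles[a] == table.alleles[b]
        if agree.all() or (~agree).all():
            continue  # no contrast within the pair
        n_tested += 1
        scores = np.where(agree, 1.0, -(g + 1.0))
        segs = _max_segments(scores)
        if not segs:
            continue
        null_max = _null_max_scores(scores, n_permutations, rng)
        for s0, s1, sc in segs:
            sim_p = float((np.sum(null_max >= sc) + 1.0) / (n_permutations + 1.0))
            results.append((a, b, s0, s1, sc, sim_p))
    for a, b, s0, s1, sc, sim_p in results:
        p_adj = min(sim_p * max(n_tested, 1), 1.0)
        if report_all or p_adj <= alpha:
            out.append(
                ConversionFragment(
                    id_a=table.ids[a], id_b=table.ids[b],
                    start_site=s0, end_site=s1 - 1,
                    start_bp=int(table.positions[s0]), end_bp=int(table.positions[s1 - 1]),
                    n_sites=s1 - s0, score=sc, sim_p=sim_p, p_adjusted=p_adj,
                )
            )
    out.sort(key=lambda f: (f.p_adjusted, -f.score))
    logger.info("sawyer_fragments: %d fragment(s) over %d informative pairs", len(out), n_tested)
    return out


def conversion_summary(
    fragments: Sequence[ConversionFragment],
    units: Sequence[DuplicatedUnit],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per unit and sequence pair, the fraction covered by significant fragments.

    Fragment spans (alignment bp) are intersected with each unit interval;
    overlapping fragments of one pair are unioned before computing
    coverage.  Units with no overlapping significant fragment are reported
    with coverage 0.
    """
    rows = []
    sig = [f for f in fragments if f.p_adjusted <= alpha]
    pairs = sorted({(f.id_a, f.id_b) for f in sig})
    for unit in units:
        u0, u1 = unit.interval.start, unit.interval.end
        for id_a, id_b in pairs or [("", "")]:
            spans = sorted(
                (max(f.start_bp, u0), min(f.end_bp + 1, u1))
                for f in sig
                if (f.id_a, f.id_b) == (id_a, id_b) and f.start_bp < u1 and f.end_bp + 1 > u0
            )
            covered = 0
            cur_lo = cur_hi = None
            for lo, hi in spans:
                if cur_hi is None or lo > cur_hi:
                    if cur_hi is not None:
                        covered += cur_hi - cur_lo
                    cur_lo, cur_hi = lo, hi
                else:
                    cur_hi = max(cur_hi, hi)
            if cur_hi is not None:
                covered += cur_hi - cur_lo
            rows.append(
                {
                    "unit": unit.label,
                    "id_a": id_a,
                    "id_b": id_b,
                    "covered_bp": covered,
                    "fraction": covered / len(unit.interval),
                }
            )
    return pd.DataFrame(rows, columns=["unit", "id_a", "id_b", "covered_bp", "fraction"])
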