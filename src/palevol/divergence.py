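"""Nucleotide- and codon-level divergence statistics.

Implements the proportion of differing sites (p-distance) with its binomial
standard error, the Nei-Gojobori pathway-counting estimator of synonymous
and nonsynonymous divergence (with optional Jukes-Cantor correction and a
seeded codon-bootstrap for standard errors), CpG-codon flagging and the
CpG-excluded variant of the estimator, a normal-approximation test of
dN = dS, a regional relative-rate comparison (Fisher's exact test), and
amino-acid change counting.

CpG dinucleotides mutate at a strongly elevated rate through deamination of
methylated cytosine; excluding codons that contain a CpG site removes that
inflation from synonymous divergence, which is the basis of the CpG-masked
estimates and of dating duplicates from CpG-only substitution counts.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from Bio.Data import CodonTable

from palevol.errors import NoDataError, ParameterError, AlphabetError, PalevolError
from palevol.seqmodel import Interval, PairwiseAlignment

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, with '*' for the three stop codons
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    GENETIC_CODE[_stop] = "*"

_BASES = "ACGT"


class CorrectionUndefinedError(PalevolError):
    """Jukes-Cantor correction requested for a proportion >= 3/4."""


# ---------------------------------------------------------------------------
# p-distance

@dataclass
class DistanceResult:
    """Proportion of differing sites with its analytic binomial SE."""

    p: float
    n_sites: int
    se: float
    mismatches: int


def p_distance(aln: PairwiseAlignment, deletion_policy: str = "pairwise") -> DistanceResult:
    """Proportion of differing nucleotide sites between two aligned rows.

    Columns where either row has a gap or an ``N`` are not comparable and are
    dropped (for two rows, pairwise and complete deletion coincide).  The
    standard error is the binomial ``sqrt(p(1-p)/n)``.
    """
    if deletion_policy not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion policy {deletion_policy!r}")
    n = mism = 0
    for x, y in zip(aln.seq_a, aln.seq_b):
        if x in _BASES and y in _BASES:
            n += 1
            if x != y:
                mism += 1
    if n == 0:
        raise NoDataError("no comparable (gap- and N-free) columns")
    p = mism / n
    return DistanceResult(p, n, math.sqrt(p * (1.0 - p) / n), mism)


# ---------------------------------------------------------------------------
# Codon alignments

@dataclass
class CodonAlignment:
    """Gap-aware aligned coding sequences partitioned into codon columns.

    Rows must have equal length, with ``(length - frame) % 3 == 0``.  Each
    codon cell must be either the all-gap triplet ``---`` or gap-free; a cell
    that straddles a gap edge is rejected, since it cannot be assigned to a
    codon.  Cells containing ``N`` are retained but treated as missing in all
    comparisons.
    """

    ids: list[str]
    rows: list[str]
    frame: int = 0

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise NoDataError("a codon alignment needs at least two rows")
        self.rows = [r.upper() for r in self.rows]
        length = len(self.rows[0])
        if any(len(r) != length for r in self.rows):
            raise ParameterError("rows have unequal lengths")
        if (length - self.frame) % 3 != 0 or self.frame < 0:
            raise ParameterError(
                f"aligned length {length} minus frame {self.frame} is not divisible by 3"
            )
        for rid, row in zip(self.ids, self.rows):
            for j in range(self.n_codons):
                cell = row[self.frame + 3 * j : self.frame + 3 * j + 3]
                n_gap = cell.count("-")
                if n_gap not in (0, 3):
                    raise AlphabetError(f"row {rid!r}: codon {j} straddles a gap ({cell})")
                if n_gap == 0 and any(c not in "ACGTN" for c in cell):
                    raise AlphabetError(f"row {rid!r}: illegal codon {cell!r} at codon {j}")

    @property
    def n_codons(self) -> int:
        return (len(self.rows[0]) - self.frame) // 3

    def codon(self, row: int, j: int) -> str:
        return self.rows[row][self.frame + 3 * j : self.frame + 3 * j + 3]

    @classmethod
    def from_ungapped(cls, ids: Sequence[str], seqs: Sequence[str]) -> "CodonAlignment":
        return cls(list(ids), list(seqs))


def _comparable(cell_a: str, cell_b: str) -> bool:
    """Both cells are gap-free, N-free, non-stop codons."""
    if "-" in cell_a or "-" in cell_b or "N" in cell_a or "N" in cell_b:
        return False
    return GENETIC_CODE[cell_a] != "*" and GENETIC_CODE[cell_b] != "*"


# ---------------------------------------------------------------------------
# Nei-Gojobori counting

@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon.

    Each of the 9 single-nucleotide neighbors contributes 1/3 of a site;
    neighbors that change the amino acid -- including changes to stop
    codons -- are nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Codons differing at several positions are resolved by averaging over all
    minimal substitution pathways with equal weights; pathways passing
    through a stop codon are excluded.  In the (rare) case where every
    pathway crosses a stop, all pathways are used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and nxt != c2:
                through_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((through_stop, sd, nd))
    valid = [(sd, nd) for stop, sd, nd in paths if not stop]
    if not valid:
        valid = [(sd, nd) for _, sd, nd in paths]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def _codon_contributions(
    codons: CodonAlignment,
    row_a: int,
    row_b: int,
    codon_mask: Optional[np.ndarray] = None,
):
    """Per-codon (S, N, Sd, Nd) arrays over comparable codon columns.

    Returns ``(index, s, n, sd, nd)`` where ``index`` holds the codon-column
    indices that entered the comparison.
    """
    idx, s_arr, n_arr, sd_arr, nd_arr = [], [], [], [], []
    for j in range(codons.n_codons):
        if codon_mask is not None and not codon_mask[j]:
            continue
        ca, cb = codons.codon(row_a, j), codons.codon(row_b, j)
        if not _comparable(ca, cb):
            continue
        s = 0.5 * (_syn_sites(ca) + _syn_sites(cb))
        sd, nd = _pathway_diffs(ca, cb)
        idx.append(j)
        s_arr.append(s)
        n_arr.append(3.0 - s)
        sd_arr.append(sd)
        nd_arr.append(nd)
    return (
        np.array(idx, dtype=int),
        np.array(s_arr),
        np.array(n_arr),
        np.array(sd_arr),
        np.array(nd_arr),
    )


def _jc(p: float) -> float:
    if p >= 0.75:
        raise CorrectionUndefinedError(f"Jukes-Cantor correction undefined for p={p:.4f} >= 3/4")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class NGResult:
    """Nei-Gojobori synonymous/nonsynonymous divergence between two rows."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    n_codons_compared: int
    n_codons_excluded: int = 0
    correction: str = "none"
    se_pS: Optional[float] = None
    se_pN: Optional[float] = None
    se_dS: Optional[float] = None
    se_dN: Optional[float] = None


def nei_gojobori(
    codons: CodonAlignment,
    row_a: int = 0,
    row_b: int = 1,
    correction: str = "none",
    codon_mask: Optional[np.ndarray] = None,
    bootstrap_reps: int = 0,
    seed: Optional[int] = None,
) -> NGResult:
    """Pathway-counting synonymous/nonsynonymous divergence.

    Site counts per codon are the fraction of the 9 single-nucleotide
    neighbors that are synonymous (averaged over the two rows); difference
    counts average over all minimal substitution pathways, excluding
    pathways through stop codons.  ``pS = Sd/S`` and ``pN = Nd/N``; with
    ``correction='jukes_cantor'`` the proportions are also corrected for
    multiple hits.  With ``bootstrap_reps > 0``, standard errors are
    estimated by resampling codon columns (seeded).
    """
    if correction not in ("none", "jukes_cantor"):
        raise ValueError(f"unknown correction {correction!r}")
    idx, s, n, sd, nd = _codon_contributions(codons, row_a, row_b, codon_mask)
    if len(idx) == 0:
        raise NoDataError("no comparable codon columns")
    excluded = 0
    if codon_mask is not None:
        excluded = int(np.sum(~np.asarray(codon_mask, bool)))

    def summarize(s, n, sd, nd):
        S, N, Sd, Nd = s.sum(), n.sum(), sd.sum(), nd.sum()
        pS = Sd / S if S > 0 else 0.0
        pN = Nd / N if N > 0 else 0.0
        if correction == "jukes_cantor":
            return pS, pN, _jc(pS), _jc(pN)
        return pS, pN, pS, pN

    pS, pN, dS, dN = summarize(s, n, sd, nd)
    res = NGResult(
        S=float(s.sum()), N=float(n.sum()), Sd=float(sd.sum()), Nd=float(nd.sum()),
        pS=pS, pN=pN, dS=dS, dN=dN,
        n_codons_compared=len(idx), n_codons_excluded=excluded, correction=correction,
    )
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        m = len(idx)
        reps = np.empty((bootstrap_reps, 4))
        for r in range(bootstrap_reps):
            take = rng.integers(0, m, size=m)
            try:
                reps[r] = summarize(s[take], n[take], sd[take], nd[take])
            except CorrectionUndefinedError:
                reps[r] = np.nan
        with np.errstate(invalid="ignore"):
            sds = np.nanstd(reps, axis=0, ddof=1)
        res.se_pS, res.se_pN, res.se_dS, res.se_dN = map(float, sds)
    return res


# ---------------------------------------------------------------------------
# CpG flagging and the CpG-excluded estimator

def flag_cpg_codons(
    codons: CodonAlignment, boundary_rule: str = "spanning"
) -> tuple[np.ndarray, int]:
    """Flag codon columns that contain a CpG site in any row.

    ``within_codon`` flags a codon whose triplet contains ``CG``;
    ``spanning`` additionally flags both codons when a ``C`` ending one
    codon is followed by a ``G`` starting the next (gap cells break the
    context).  Returns the boolean flag vector and the flagged count.
    """
    if boundary_rule not in ("within_codon", "spanning"):
        raise ValueError(f"unknown boundary rule {boundary_rule!r}")
    nc = codons.n_codons
    flags = np.zeros(nc, dtype=bool)
    for row in range(len(codons.rows)):
        cells = [codons.codon(row, j) for j in range(nc)]
        for j, cell in enumerate(cells):
            if "CG" in cell:
                flags[j] = True
            if boundary_rule == "spanning" and j + 1 < nc:
                if cell.endswith("C") and cells[j + 1].startswith("G"):
                    flags[j] = True
                    flags[j + 1] = True
    return flags, int(flags.sum())


def ng_excluding_cpg(
    codons: CodonAlignment,
    row_a: int = 0,
    row_b: int = 1,
    boundary_rule: str = "spanning",
    correction: str = "none",
    bootstrap_reps: int = 0,
    seed: Optional[int] = None,
) -> NGResult:
    """Nei-Gojobori divergence restricted to codons without CpG sites."""
    flags, n_flagged = flag_cpg_codons(codons, boundary_rule)
    if n_flagged == codons.n_codons:
        raise NoDataError("all codon columns are CpG-flagged")
    res = nei_gojobori(
        codons, row_a, row_b, correction=correction, codon_mask=~flags,
        bootstrap_reps=bootstrap_reps, seed=seed,
    )
    res.n_codons_excluded = n_flagged
    return res


# ---------------------------------------------------------------------------
# dN = dS test

@dataclass
class DnDsTest:
    z: float
    p_one_sided: float
    p_two_sided: float
    dn_ds_ratio: Optional[float]
    difference: float


def dnds_z_test(ng: NGResult) -> DnDsTest:
    """Normal-approximation test of H0: dN = dS.

    Requires bootstrap standard errors on the result (compute the
    :class:`NGResult` with ``bootstrap_reps > 0``).  ``z = (dN - dS) /
    sqrt(se_dN^2 + se_dS^2)``; the one-sided p-value is for the observed
    direction.  When dS = 0 the ratio is undefined and reported as ``None``
    while the test is still carried out on the difference scale.
    """
    if ng.se_dS is None or ng.se_dN is None:
        raise NoDataError("dnds_z_test needs bootstrap SEs; rerun with bootstrap_reps > 0")
    denom = math.hypot(ng.se_dS, ng.se_dN)
    diff = ng.dN - ng.dS
    if denom == 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        z = diff / denom
    p_two = 2.0 * stats.norm.sf(abs(z))
    p_one = stats.norm.sf(abs(z))
    ratio = ng.dN / ng.dS if ng.dS > 0 else None
    return DnDsTest(z=float(z), p_one_sided=float(min(p_one, 1.0)),
                    p_two_sided=float(min(p_two, 1.0)), dn_ds_ratio=ratio, difference=diff)


# ---------------------------------------------------------------------------
# Regional relative-rate comparison

@dataclass
class RegionRateReport:
    metric: str
    rate_in: float
    rate_out: float
    diffs_in: float
    sites_in: float
    diffs_out: float
    sites_out: float
    odds_ratio: float
    p_value: float
    table: list[list[int]]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def region_rate_compare(
    codons: CodonAlignment,
    row_ref: int,
    row_test: int,
    region: Interval,
    metric: str = "nonsyn",
) -> RegionRateReport:
    """Compare substitution rates inside vs outside a CDS region.

    ``region`` is an interval in CDS nucleotide coordinates (alignment
    columns); a codon belongs to the region when its triplet overlaps it.
    The in-region and out-region difference proportions against the
    reference row are compared with Fisher's exact test on the 2x2 table of
    differences vs non-differing site mass (site masses rounded half-up to
    integers).
    """
    if metric not in ("nonsyn", "syn"):
        raise ValueError(f"unknown metric {metric!r}")
    nc = codons.n_codons
    length = 3 * nc
    if region.start <= 0 and region.end >= length:
        raise ParameterError("region covers the whole CDS; no outside codons to compare")
    in_mask = np.zeros(nc, dtype=bool)
    for j in range(nc):
        if region.start < 3 * j + 3 and 3 * j < region.end:
            in_mask[j] = True

    def tally(mask):
        idx, s, n, sd, nd = _codon_contributions(codons, row_ref, row_test, mask)
        if len(idx) == 0:
            raise NoDataError("no comparable codons in one of the regions")
        if metric == "syn":
            return float(sd.sum()), float(s.sum())
        return float(nd.sum()), float(n.sum())

    d_in, m_in = tally(in_mask)
    d_out, m_out = tally(~in_mask)
    table = [
        [_round_half_up(d_in), max(_round_half_up(m_in - d_in), 0)],
        [_round_half_up(d_out), max(_round_half_up(m_out - d_out), 0)],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return RegionRateReport(
        metric=metric,
        rate_in=d_in / m_in, rate_out=d_out / m_out,
        diffs_in=d_in, sites_in=m_in, diffs_out=d_out, sites_out=m_out,
        odds_ratio=float(odds), p_value=float(p), table=table,
    )


# ---------------------------------------------------------------------------
# Amino-acid changes

def count_amino_acid_changes(
    codons: CodonAlignment,
    row_a: int = 0,
    row_b: int = 1,
    region: Optional[Interval] = None,
) -> tuple[int, int]:
    """Count codon columns whose translations differ, split by region.

    Returns ``(total_changes, in_region_changes)``.  Codon columns with an
    internal stop codon are skipped with a warning.
    """
    total = in_region = 0
    for j in range(codons.n_codons):
        ca, cb = codons.codon(row_a, j), codons.codon(row_b, j)
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        aa, ab = GENETIC_CODE[ca], GENETIC_CODE[cb]
        if "*" in (aa, ab):
            logger.warning("internal stop codon at codon %d (%s/%s); skipped", j, ca, cb)
            continue
        if aa != ab:
            total += 1
            if region is not None and region.start < 3 * j + 3 and 3 * j < region.end:
                in_region += 1
    return total, in_region
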