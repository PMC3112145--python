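"""Synthetic-data generators with full ground truth.

Every analysis stage in this package can be exercised without downloads:
the generators here produce (i) codon-alignment pairs evolved under a
continuous-time model with CpG hypermutability and a nonsynonymous
acceptance rate omega, (ii) palindromic loci assembled from duplicated
units whose arms are homogenized by simulated gene-conversion tracts
around a protected divergent island, and (iii) multiple alignments evolved
site-independently down a given tree.  Each generator returns a truth
record sufficient to verify what downstream estimators recover.

Defaults emulate the study conditions of a young primate palindrome
cluster: ~10-20 kb duplicated units, arm identity far above 95% maintained
by conversion, a protected island of ~700 bp at ~2% divergence over a
near-zero background, and 315-codon coding alignments in which CpG-codon
substitution rates are strongly elevated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from palevol.divergence import GENETIC_CODE, CodonAlignment, _pathway_diffs, flag_cpg_codons
from palevol.errors import ParameterError
from palevol.phylogeny import PhyloTree
from palevol.seqmodel import Interval, NucSequence, PairwiseAlignment, reverse_complement

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# Codon-pair simulation

@dataclass
class CodonSimTruth:
    """Ground truth for one simulated coding-sequence pair."""

    n_codons: int
    t: float
    omega: float
    cpg_mult: float
    seed: Optional[int]
    n_events: int
    n_events_syn: int
    n_events_nonsyn: int
    n_events_cpg_context: int
    # realized difference counts on the emitted pair (pathway-classified)
    syn_diffs: float
    nonsyn_diffs: float
    cpg_flagged_codons: int
    syn_diffs_cpg: float
    syn_diffs_noncpg: float
    event_log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "event_log"}
        d["n_logged_events"] = len(self.event_log)
        return d


def _sample_cds(n_codons: int, rng: np.random.Generator, cpg_q: float) -> list[str]:
    """Random CpG-depleted CDS without internal stops.

    Nucleotides follow a first-order chain with ``P(G | previous C) =
    cpg_q`` (uniform otherwise), emulating the CpG depletion of mammalian
    DNA; stop codons are resampled.
    """
    seq: list[str] = []
    prev = "A"
    for _ in range(n_codons):
        while True:
            codon = []
            p = prev
            for _ in range(3):
                if p == "C":
                    probs = [(1 - cpg_q) / 3] * 4
                    probs[_BASE_IDX["G"]] = cpg_q
                else:
                    probs = [0.25] * 4
                b = _BASES[rng.choice(4, p=probs)]
                codon.append(b)
                p = b
            codon = "".join(codon)
            if GENETIC_CODE[codon] != "*":
                seq.append(codon)
                prev = codon[-1]
                break
    return list("".join(seq))


def _site_target_rates(seq: list[str], pos: int, omega: float, cpg_mult: float):
    """Rates of the three substitutions at one site in its current context."""
    L = len(seq)
    base = seq[pos]
    in_cpg = (pos > 0 and seq[pos - 1] == "C" and base == "G") or (
        base == "C" and pos + 1 < L and seq[pos + 1] == "G"
    )
    mult = cpg_mult if in_cpg else 1.0
    c0 = pos - pos % 3
    codon = "".join(seq[c0 : c0 + 3])
    aa = GENETIC_CODE[codon]
    out = []
    for b in _BASES:
        if b == base:
            continue
        mutant = codon[: pos - c0] + b + codon[pos - c0 + 1 :]
        maa = GENETIC_CODE[mutant]
        if maa == "*":
            rate = 0.0
        elif maa == aa:
            rate = mult / 3.0
        else:
            rate = mult * omega / 3.0
        out.append((b, rate, maa == aa, in_cpg))
    return out


def simulate_cds_pair(
    n_codons: int = 315,
    t: float = 0.09,
    omega: float = 0.9,
    cpg_mult: float = 20.0,
    seed: Optional[int] = None,
    cpg_q: float = 0.11,
) -> tuple[NucSequence, NucSequence, CodonSimTruth]:
    """Evolve a coding-sequence pair with CpG hypermutability.

    One lineage of total length ``t`` (expected substitutions per neutral
    non-CpG site) is evolved from a random CpG-depleted start CDS by a
    Gillespie walk: each site mutates at rate 1 (per unit branch length),
    multiplied by ``cpg_mult`` while the site sits in a CG dinucleotide
    (context is re-evaluated at every event, across codon boundaries), with
    nonsynonymous changes accepted at relative rate ``omega`` and changes
    creating stop codons rejected.  The defaults reproduce the regime of a
    315-codon primate gene pair with ~14% of codons carrying CpG sites and
    synonymous divergence dropping roughly from 13% to 8% when CpG codons
    are excluded.
    """
    if n_codons < 10:
        raise ParameterError("n_codons must be >= 10")
    if t < 0 or cpg_mult < 1:
        raise ParameterError("need t >= 0 and cpg_mult >= 1")
    rng = np.random.default_rng(seed)
    anc = _sample_cds(n_codons, rng, cpg_q)
    seq = list(anc)
    L = len(seq)

    def codon_rate(c: int) -> float:
        return sum(
            r for p in range(3 * c, 3 * c + 3) for _, r, _, _ in _site_target_rates(seq, p, omega, cpg_mult)
        )

    codon_rates = np.array([codon_rate(c) for c in range(n_codons)])
    tau = 0.0
    events = []
    while True:
        R = codon_rates.sum()
        if R <= 0:
            break
        tau += rng.exponential(1.0 / R)
        if tau > t:
            break
        c = rng.choice(n_codons, p=codon_rates / R)
        choices = []
        for p in range(3 * c, 3 * c + 3):
            for b, r, syn, cpg in _site_target_rates(seq, p, omega, cpg_mult):
                if r > 0:
                    choices.append((p, b, r, syn, cpg))
        weights = np.array([ch[2] for ch in choices])
        pick = choices[rng.choice(len(choices), p=weights / weights.sum())]
        pos, newb, _, syn, cpg = pick
        events.append({"time": tau, "pos": pos, "from": seq[pos], "to": newb, "syn": syn, "cpg_context": cpg})
        seq[pos] = newb
        for cc in (c - 1, c, c + 1):
            if 0 <= cc < n_codons:
                codon_rates[cc] = codon_rate(cc)

    sa, sb = "".join(anc), "".join(seq)
    aln = CodonAlignment.from_ungapped(["ancestor", "derived"], [sa, sb])
    flags, n_flagged = flag_cpg_codons(aln, "spanning")
    syn_d = nonsyn_d = syn_cpg = 0.0
    for j in range(n_codons):
        sd, nd = _pathway_diffs(aln.codon(0, j), aln.codon(1, j))
        syn_d += sd
        nonsyn_d += nd
        if flags[j]:
            syn_cpg += sd
    truth = CodonSimTruth(
        n_codons=n_codons, t=t, omega=omega, cpg_mult=cpg_mult, seed=seed,
        n_events=len(events),
        n_events_syn=sum(e["syn"] for e in events),
        n_events_nonsyn=sum(not e["syn"] for e in events),
        n_events_cpg_context=sum(e["cpg_context"] for e in events),
        syn_diffs=syn_d, nonsyn_diffs=nonsyn_d,
        cpg_flagged_codons=n_flagged,
        syn_diffs_cpg=syn_cpg, syn_diffs_noncpg=syn_d - syn_cpg,
        event_log=events,
    )
    return NucSequence("sim_cds_a", sa), NucSequence("sim_cds_b", sb), truth


# ---------------------------------------------------------------------------
# Palindrome locus simulation

@dataclass
class LocusTruth:
    """Ground truth for a simulated palindromic locus."""

    unit_length: int
    arm_units: int
    loop_units: int
    background_div: float
    conversion_rate: float
    seed: Optional[int]
    arm1: Interval
    loop: Interval
    arm2: Interval
    units: list[Interval]
    conversion_tracts: list[Interval]   # arm coordinates
    island: Optional[Interval]          # arm coordinates
    island_divergence: Optional[float]  # realized arm1-vs-arm2 divergence inside
    background_divergence: float        # realized divergence outside island
    arm2_plus: str                      # arm2 in arm1 orientation (alignment row)
    outgroup: Optional[NucSequence]
    event_log: list = field(default_factory=list)

    def arm_alignment(self, seq: NucSequence) -> PairwiseAlignment:
        """Ungapped alignment of arm1 vs the reverse complement of arm2."""
        arm1 = seq.residues[self.arm1.start : self.arm1.end]
        return PairwiseAlignment("arm1", "arm2_rc", arm1, self.arm2_plus)

    def to_dict(self) -> dict:
        iv = lambda x: None if x is None else [x.start, x.end]
        return {
            "unit_length": self.unit_length,
            "arm_units": self.arm_units,
            "loop_units": self.loop_units,
            "background_div": self.background_div,
            "conversion_rate": self.conversion_rate,
            "seed": self.seed,
            "arm1": iv(self.arm1), "loop": iv(self.loop), "arm2": iv(self.arm2),
            "units": [[u.start, u.end, u.label] for u in self.units],
            "conversion_tracts": [[t.start, t.end] for t in self.conversion_tracts],
            "island": iv(self.island),
            "island_divergence": self.island_divergence,
            "background_divergence": self.background_divergence,
            "n_logged_events": len(self.event_log),
        }


def _mutate(arr: np.ndarray, idx: np.ndarray, rng: np.random.Generator) -> list:
    """Substitute positions ``idx`` of a byte array with a different base."""
    log = []
    for i in idx:
        old = arr[i]
        alt = [b for b in b"ACGT" if b != old]
        new = alt[rng.integers(3)]
        arr[i] = new
        log.append(int(i))
    return log


def simulate_palindrome_locus(
    unit_length: int = 12000,
    arm_units: int = 3,
    loop_units: int = 1,
    background_div: float = 0.002,
    conversion_rate: float = 8.0,
    island: Optional[tuple[int, float, Optional[int]]] = (673, 0.02, None),
    seed: Optional[int] = None,
    tract_mean: int = 500,
    outgroup_div: Optional[float] = 0.05,
) -> tuple[NucSequence, LocusTruth]:
    """Assemble a palindromic locus with conversion-homogenized arms.

    The locus is ``arm1 + loop + revcomp(arm2)`` where arm2 begins as a
    copy of arm1 (each arm a concatenation of ``arm_units`` units of
    ``unit_length`` bp).  Point divergence at ``background_div`` is applied
    to arm2; a Poisson(``conversion_rate``) number of conversion tracts
    (geometric length, mean ``tract_mean``) then overwrite arm2 with arm1
    sequence -- everywhere except inside the protected island -- and the
    island finally receives additional divergence at its own rate.
    ``island`` is ``(length, divergence, start_in_arm)`` with ``None``
    start centering the island on the middle unit; pass ``island=None`` for
    no island.  An optional outgroup arm at ``outgroup_div`` gives
    conversion detection its "others differ" context.
    """
    if island is not None:
        isl_len, isl_div, isl_pos = island
        if not (0 <= isl_div <= 0.25) or not (0 <= background_div <= 0.25):
            raise ParameterError("divergences must lie in [0, 0.25]")
        if isl_len >= arm_units * unit_length:
            raise ParameterError("island longer than the arm")
    elif not (0 <= background_div <= 0.25):
        raise ParameterError("divergences must lie in [0, 0.25]")

    rng = np.random.default_rng(seed)
    A = arm_units * unit_length
    Lp = loop_units * unit_length
    arm1 = rng.integers(0, 4, size=A)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    arm1 = lut[arm1]
    arm2 = arm1.copy()
    event_log = []

    # background divergence on arm2
    bg_idx = np.flatnonzero(rng.random(A) < background_div)
    for i in _mutate(arm2, bg_idx, rng):
        event_log.append({"type": "background", "pos": i})

    # protected island span
    isl_iv = None
    if island is not None:
        if isl_pos is None:
            mid_unit = arm_units // 2
            isl_pos = mid_unit * unit_length + (unit_length - isl_len) // 2
        if isl_pos < 0 or isl_pos + isl_len > A:
            raise ParameterError("island does not fit inside the arm")
        isl_iv = Interval("locus", isl_pos, isl_pos + isl_len, "+", "island")

    # conversion tracts copy arm1 -> arm2, skipping the island
    tracts = []
    n_tracts = rng.poisson(conversion_rate)
    for _ in range(n_tracts):
        start = int(rng.integers(0, A))
        length = int(rng.geometric(1.0 / tract_mean))
        end = min(start + length, A)
        tracts.append(Interval("locus", start, end, "+", "conversion"))
        for i in range(start, end):
            if isl_iv is not None and isl_iv.contains(i):
                event_log.append({"type": "conversion_blocked", "pos": i})
                continue
            if arm2[i] != arm1[i]:
                event_log.append({"type": "conversion_copy", "pos": i})
            arm2[i] = arm1[i]

    # island divergence (applied last; conversion never reduces it).  The
    # island is the planted signal, so its mutation count is exact --
    # round(length x divergence) positions sampled without replacement --
    # rather than a binomial draw; the truth record then carries a known
    # planted divergence instead of a noisy realization.
    if isl_iv is not None and isl_div > 0:
        n_mut = int(round(len(isl_iv) * isl_div))
        within = rng.choice(len(isl_iv), size=n_mut, replace=False) + isl_iv.start
        for i in _mutate(arm2, np.sort(within), rng):
            event_log.append({"type": "island", "pos": i})

    loop_seq = lut[rng.integers(0, 4, size=Lp)]
    arm2_plus = arm2.tobytes().decode()
    genome = arm1.tobytes().decode() + loop_seq.tobytes().decode() + reverse_complement(arm2_plus)
    seq = NucSequence("sim_locus", genome)

    units = []
    for u in range(arm_units):
        units.append(Interval("sim_locus", u * unit_length, (u + 1) * unit_length, "+", f"u{u + 1}"))
    for u in range(arm_units):
        g0 = A + Lp + u * unit_length
        units.append(
            Interval("sim_locus", g0, g0 + unit_length, "-", f"u{arm_units - u}'")
        )

    arm1_str = arm1.tobytes().decode()
    mism = np.frombuffer(arm1_str.encode(), "S1") != np.frombuffer(arm2_plus.encode(), "S1")
    if isl_iv is not None:
        inside = mism[isl_iv.start : isl_iv.end]
        outside = np.concatenate([mism[: isl_iv.start], mism[isl_iv.end :]])
        realized_isl = float(inside.mean())
    else:
        outside = mism
        realized_isl = None
    realized_bg = float(outside.mean()) if len(outside) else 0.0

    outgroup = None
    if outgroup_div:
        og = arm1.copy()
        og_idx = np.flatnonzero(rng.random(A) < outgroup_div)
        _mutate(og, og_idx, rng)
        outgroup = NucSequence("sim_outgroup_arm", og.tobytes().decode())

    truth = LocusTruth(
        unit_length=unit_length, arm_units=arm_units, loop_units=loop_units,
        background_div=background_div, conversion_rate=conversion_rate, seed=seed,
        arm1=Interval("sim_locus", 0, A, "+", "arm1"),
        loop=Interval("sim_locus", A, A + Lp, "+", "loop"),
        arm2=Interval("sim_locus", A + Lp, 2 * A + Lp, "-", "arm2"),
        units=units,
        conversion_tracts=tracts,
        island=isl_iv,
        island_divergence=realized_isl,
        background_divergence=realized_bg,
        arm2_plus=arm2_plus,
        outgroup=outgroup,
        event_log=event_log,
    )
    return seq, truth


# ---------------------------------------------------------------------------
# Family alignment simulation

def simulate_family_alignment(
    tree: PhyloTree, n_sites: int = 2000, seed: Optional[int] = None
) -> tuple[dict[str, str], PhyloTree]:
    """Evolve i.i.d. sites down a tree under the Jukes-Cantor model.

    Branch lengths are expected substitutions per site; along a branch of
    length ``b`` each site changes to one of the three other bases with
    total probability ``(3/4)(1 - exp(-4b/3))``.  Returns the leaf
    sequences keyed by taxon label, plus the (unchanged) truth tree.
    """
    rng = np.random.default_rng(seed)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    root_seq = lut[rng.integers(0, 4, size=n_sites)]
    seqs: dict[int, np.ndarray] = {id(tree.tree.seed_node): root_seq}
    leaves: dict[str, str] = {}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        b = node.edge.length or 0.0
        p_change = 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))
        child = parent_seq.copy()
        hit = np.flatnonzero(rng.random(n_sites) < p_change)
        if len(hit):
            shift = rng.integers(1, 4, size=len(hit))
            idxs = np.searchsorted(lut, child[hit])  # lut is sorted (ACGT)
            child[hit] = lut[(idxs + shift) % 4]
        seqs[id(node)] = child
        if node.is_leaf():
            leaves[node.taxon.label] = child.tobytes().decode()
    return leaves, tree
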