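"""Core domain types and I/O for the standard formats the pipeline touches.

Sequences are plain uppercase nucleotide strings over ``{A,C,G,T,N}``; ``N``
marks missing data (assembly gaps) and is excluded from every site count
downstream.  All internal coordinates are 0-based half-open on the plus
strand; minus-strand features carry a strand flag and are never stored as
reverse-complemented coordinates.  The module also implements the exon-phase
computation used to compare gene structures across species.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from palevol.errors import AlphabetError, EmptyInputError, MalformedIntervalError

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(residues: str) -> str:
    """Reverse complement of an ``{A,C,G,T,N}`` string."""
    return residues.translate(_COMPLEMENT)[::-1]


def _validate_residues(residues: str, label: str) -> str:
    residues = residues.upper()
    for i, ch in enumerate(residues):
        if ch not in ALPHABET:
            raise AlphabetError(
                f"sequence {label!r}: illegal residue {ch!r} at position {i}"
            )
    return residues


@dataclass
class NucSequence:
    """A named nucleotide sequence over ``{A,C,G,T,N}``.

    Residues are case-normalized to uppercase on construction; any other
    symbol (including RNA ``U``) raises :class:`AlphabetError` naming the
    offending position.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise EmptyInputError(f"sequence {self.id!r} is empty")
        self.residues = _validate_residues(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id + "_rc", reverse_complement(self.residues), self.description)


@dataclass(frozen=True)
class Interval:
    """A genomic interval: 0-based half-open, with strand and free-text label."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise MalformedIntervalError(
                f"interval {self.label or self.seq_id!r}: bad span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise MalformedIntervalError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def overlap_bp(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneModel:
    """Exon structure of one gene; only protein-coding exons are listed.

    ``exon_sizes`` are the coding lengths (bp) of the coding exons in 5'->3'
    order on the coding strand; genomic ``exons`` intervals are optional and,
    when given, must be ordered and non-overlapping.
    """

    gene_id: str
    exon_sizes: list[int]
    coding: Optional[list[bool]] = None
    exons: Optional[list[Interval]] = None

    def __post_init__(self) -> None:
        if not self.exon_sizes or any(s < 1 for s in self.exon_sizes):
            raise MalformedIntervalError(f"gene {self.gene_id!r}: exon sizes must be positive")
        if self.coding is None:
            self.coding = [True] * len(self.exon_sizes)
        if self.exons is not None:
            for a, b in zip(self.exons, self.exons[1:]):
                if a.end > b.start:
                    raise MalformedIntervalError(
                        f"gene {self.gene_id!r}: exons overlap or are unordered"
                    )

    @property
    def coding_sizes(self) -> list[int]:
        return [s for s, c in zip(self.exon_sizes, self.coding) if c]


@dataclass
class PairwiseAlignment:
    """Two gapped rows of equal length; no column may be gap in both rows."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise MalformedIntervalError(
                f"alignment {self.id_a}/{self.id_b}: row lengths differ "
                f"({len(self.seq_a)} vs {len(self.seq_b)})"
            )
        for i, (x, y) in enumerate(zip(self.seq_a, self.seq_b)):
            if x == "-" and y == "-":
                raise MalformedIntervalError(f"column {i} is gap in both rows")
            if x != "-" and x not in ALPHABET:
                raise AlphabetError(f"row {self.id_a!r}: illegal residue {x!r} at column {i}")
            if y != "-" and y not in ALPHABET:
                raise AlphabetError(f"row {self.id_b!r}: illegal residue {y!r} at column {i}")

    def __len__(self) -> int:
        return len(self.seq_a)

    def column_map(self, row: str = "a") -> list[int]:
        """Map alignment columns to ungapped coordinates (-1 at gap columns)."""
        seq = self.seq_a if row == "a" else self.seq_b
        out, pos = [], 0
        for ch in seq:
            if ch == "-":
                out.append(-1)
            else:
                out.append(pos)
                pos += 1
        return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[NucSequence]:
    """Read a nucleotide FASTA file into a list of :class:`NucSequence`.

    Record order is preserved and lowercase residues are normalized to
    uppercase.  An empty file raises :class:`EmptyInputError`; an illegal
    residue raises :class:`AlphabetError` naming the position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    out = [NucSequence(r.id, str(r.seq), r.description) for r in records]
    logger.info("read %d sequences from %s", len(out), path)
    return out


def write_fasta(path, seqs: Iterable[NucSequence]) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description=s.description or "") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Intervals: BED and NCBI-span dialects

_SPAN_RE = re.compile(r"^(?:(complementary)\s+)?(\d+)(?:\.\.|‥)(\d+)$")


def parse_ncbi_span(seq_id: str, span: str, label: str = "") -> Interval:
    """Parse an NCBI-style span such as ``"complementary 151952946‥151957859"``.

    NCBI spans are 1-based inclusive; ``complementary`` marks the minus
    strand.  The result is in the internal 0-based half-open convention.
    """
    m = _SPAN_RE.match(span.strip())
    if not m:
        raise MalformedIntervalError(f"cannot parse NCBI span {span!r}")
    strand = "-" if m.group(1) else "+"
    start1, end1 = int(m.group(2)), int(m.group(3))
    if start1 < 1 or start1 > end1:
        raise MalformedIntervalError(f"bad NCBI span {span!r}")
    return Interval(seq_id, start1 - 1, end1, strand, label)


def format_ncbi_span(iv: Interval) -> str:
    """Inverse of :func:`parse_ncbi_span` (round-trip identity)."""
    prefix = "complementary " if iv.strand == "-" else ""
    return f"{prefix}{iv.start + 1}..{iv.end}"


def read_intervals(path, coordinate_dialect: str = "bed") -> list[Interval]:
    """Read intervals from BED 4+ (``bed``) or a span table (``ncbi``).

    The ``ncbi`` dialect is a TSV of ``seq_id <TAB> span [<TAB> label]`` with
    spans as accepted by :func:`parse_ncbi_span`.  All results are in the
    internal 0-based half-open convention.
    """
    if coordinate_dialect not in ("bed", "ncbi"):
        raise ValueError(f"unknown coordinate dialect {coordinate_dialect!r}")
    out: list[Interval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if coordinate_dialect == "bed":
                    seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
                    label = fields[3] if len(fields) > 3 else ""
                    strand = fields[5] if len(fields) > 5 else "+"
                    out.append(Interval(seq_id, start, end, strand, label))
                else:
                    seq_id, span = fields[0], fields[1]
                    label = fields[2] if len(fields) > 2 else ""
                    out.append(parse_ncbi_span(seq_id, span, label))
            except (MalformedIntervalError, ValueError, IndexError) as exc:
                raise MalformedIntervalError(f"{path}:{lineno}: {exc}") from exc
    if not out:
        raise EmptyInputError(f"no intervals in {path}")
    logger.info("read %d intervals from %s", len(out), path)
    return out


def write_intervals(path, intervals: Iterable[Interval], coordinate_dialect: str = "bed") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            if coordinate_dialect == "bed":
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.seq_id}\t{format_ncbi_span(iv)}\t{iv.label}\n")


def read_gene_models(path) -> dict[str, GeneModel]:
    """Read a TSV gene-model table: gene_id, exon index, size (bp), coding flag."""
    rows: dict[str, list[tuple[int, int, bool]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene_id"):
                continue
            gene_id, idx, size, coding = line.split("\t")[:4]
            rows.setdefault(gene_id, []).append((int(idx), int(size), coding in ("1", "true", "True")))
    if not rows:
        raise EmptyInputError(f"no gene models in {path}")
    models = {}
    for gene_id, exons in rows.items():
        exons.sort()
        models[gene_id] = GeneModel(
            gene_id,
            [s for _, s, _ in exons],
            coding=[c for _, _, c in exons],
        )
    logger.info("read %d gene models from %s", len(models), path)
    return models


# ---------------------------------------------------------------------------
# Exon phases

Phase = tuple[int, int]


def exon_phases(model: Union[GeneModel, Sequence[int]], initial_phase: int = 0) -> list[Phase]:
    """Start/end phase of each coding exon, accumulating sizes modulo 3.

    The phase of a boundary is the number of nucleotides of the interrupted
    codon that lie 5' of it (0, 1 or 2).  ``start_phase[i] = end_phase[i-1]``
    and ``end_phase[i] = (start_phase[i] + size[i]) mod 3``.
    """
    if initial_phase not in (0, 1, 2):
        raise ValueError("initial_phase must be 0, 1 or 2")
    sizes = model.coding_sizes if isinstance(model, GeneModel) else list(model)
    phases: list[Phase] = []
    phase = initial_phase
    for size in sizes:
        end = (phase + size) % 3
        phases.append((phase, end))
        phase = end
    return phases


@dataclass
class PhaseConservationReport:
    """Per-exon phase agreement across species profiles."""

    species: list[str]
    n_shared: int
    agree: list[bool]          # per shared exon: all comparable phases identical
    comparable: list[bool]     # per shared exon: every species has a phase
    mismatches: list[int]      # shared exon indices where phases disagree
    conserved: bool


def compare_phase_profiles(
    profiles: Mapping[str, Sequence[Optional[Phase]]],
) -> PhaseConservationReport:
    """Compare exon-phase profiles across >=2 species.

    Profiles are aligned by exon index; ``None`` entries mark untranslated or
    unshared exons and are reported as "not comparable" rather than as
    mismatches.  ``conserved`` is true when every comparable shared exon has
    identical phases in all species.
    """
    if len(profiles) < 2:
        raise EmptyInputError("need at least two phase profiles")
    species = list(profiles)
    n_shared = min(len(v) for v in profiles.values())
    agree, comparable, mismatches = [], [], []
    for i in range(n_shared):
        phases = [profiles[s][i] for s in species]
        comp = all(p is not None for p in phases)
        ok = comp and len({tuple(p) for p in phases}) == 1
        comparable.append(comp)
        agree.append(ok)
        if comp and not ok:
            mismatches.append(i)
    conserved = not mismatches and any(comparable)
    return PhaseConservationReport(species, n_shared, agree, comparable, mismatches, conserved)
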