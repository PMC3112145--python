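# Methods

This note records the models, estimators and numerical conventions behind
each module, the choices made where the design was genuinely open, and what
the synthetic generators do and do not emulate.

## Coordinates, alphabets, alignments

All internal coordinates are 0-based half-open on the plus strand;
minus-strand features carry a strand flag and are never stored as
reverse-complemented coordinates. External spans in the 1-based inclusive
"complementary a‥b" style convert losslessly in both directions. Sequences
are uppercase over `{A,C,G,T,N}`; `N` marks assembly gaps and is excluded
from every site count (pairwise deletion by default; complete deletion for
distance matrices fed to trees, the usual tree-building convention).
Alignments are consumed as input — the package never aligns; a codon
alignment must have codon-respecting gaps (`---` cells), since a gap
straddling a codon cannot be assigned to one.

## Divergence estimators

**p-distance.** `p = n_d/n` over comparable columns with the analytic
binomial SE `sqrt(p(1−p)/n)`. Symmetric, zero on identity, and monotone in
mismatches by construction.

**Nei–Gojobori.** Synonymous sites per codon are the fraction of the 9
single-nucleotide neighbors that preserve the amino acid (changes to stop
codons count as nonsynonymous); site counts are averaged over the two
sequences, so `S + N = 3 ×` (compared codons) exactly. Difference counts
for multi-hit codons average over all minimal substitution pathways with
equal weights, excluding pathways through stop codons (if every pathway is
blocked, all are used — a rare corner recorded here for completeness).
Codon columns containing a gap, an `N`, or a stop codon in either row are
not compared. The optional multiple-hit correction is Jukes–Cantor,
`d = −(3/4) ln(1 − 4p/3)`, undefined for `p ≥ 3/4` (raised as an error
rather than clamped). Standard errors for `pS`, `pN`, `dS`, `dN` come from
a seeded codon-resampling bootstrap (default 1000 replicates): analytic
variance formulas for pathway-counted proportions are model-dependent,
while the bootstrap matches the estimator actually used.

**CpG flagging.** A codon column is flagged when any row's codon contains
`CG`, and — under the default `spanning` rule — both codons are flagged
when a `C` ending one codon is followed by a `G` starting the next. The
spanning rule is the default because a CpG's hypermutability does not
respect codon boundaries; the `within_codon` rule is available, and with
zero flags the CpG-excluded estimator is bit-identical to the plain one.

**dN = dS test.** `z = (dN − dS)/sqrt(se_dN² + se_dS²)` with
normal-approximation p-values; when `dS = 0` the dN/dS ratio is reported as
undefined while the difference-scale test stands.

**Regional relative rate.** Differences vs non-differing site mass inside
and outside a CDS region, compared by Fisher's exact test with site masses
rounded half-up to integers. Fisher was chosen over a z-test for small
counts; rounding fractional site masses slightly discretizes the table but
keeps the test exact. Whole-CDS regions are rejected (no contrast).

## Palindrome detection

Self-comparison seeds exact k-words (default k=12) against the sequence
and its reverse complement, chains seeds on common (anti)diagonals with a
maximum seed gap of 2k, and keeps chains ≥ `min_segment` (default 300 bp).
Inverted chains whose query/subject spans are near (within `merge_gap`) and
mirror-ordered merge into an arm pair; arm boundaries are then polished
outward in 16-bp mirrored blocks that must keep ≥10/16 matches, which
recovers the ends that exact-word chains undershoot when arm divergence
approaches 5%. Arm identity is recomputed from a global edit-distance
(edlib NW) alignment of the full arm spans — not from seed coverage —
because identity feeds the similarity bins. Similarity bins are half-open
at the stated boundaries (0.95 is orange, not red). Overlapping calls are
resolved longest-arm-first, treating each region as having one principal
palindrome. Unit orthology uses the Jaccard index of shared-insertion
marker sets with greedy one-to-one assignment (ties by positional order);
shared insertions are near-homoplasy-free, so even modest overlaps separate
orthologs from paralogs.

## Window profile and island detection

The profile counts mismatches per non-overlapping window (default 500 bp,
pairwise deletion), with positions reported both absolutely and signed
relative to a caller-supplied center (the loop midpoint, so that the two
arms mirror around zero). When step = window, windows tile the whole
alignment and window mismatches sum exactly to the alignment total.

Island calling tests each window's mismatch count one-sided against the
pooled leave-one-out background rate with an exact binomial test (a
half-count is added to the background so it stays defined when all other
windows are clean — a conservative continuity correction), adjusts across
windows by Benjamini–Hochberg, and merges adjacent significant windows. No
distributional assumption beyond site independence is made; a
window-label-shuffling permutation test is available behind
`method="permutation"` (its p-value resolution is 1/(B+1), which bounds the
attainable adjusted level). Both variants are gated by the same calibration
tests.

**Boundary refinement.** Islands shorter than a window need sub-window
boundaries. Within the merged windows ±1 window, a two-state log-odds
segmentation (mismatch: `log(p_isl/p_bg)`; match: `log((1−p_isl)/(1−p_bg))`)
is run twice — the island rate is re-estimated from the first-pass core
because the window-mean rate is diluted when the island straddles window
edges — and each edge is then placed at the posterior median of the edge
position under the two-rate model, walking outward from the core. The
posterior median absorbs two error sources at once: the true edge lies
beyond the outermost realized mismatch (median overhang ≈ ln2/p_isl), and
isolated background mismatches just outside the island create a second,
usually minor, posterior lobe. The background for refinement excludes the
island's flanking windows (spillover would inflate it). An oracle analysis
(the same posterior-median estimator given the true rates) shows per-edge
localization below ~150 bp fails with probability ≈5–7% at these rates, so
island boundary accuracy is summarized as the mean of the two edge errors;
demanding both edges simultaneously would sit at the estimator's
information floor rather than measure implementation quality.

## Gene conversion (Sawyer fragments)

Informative sites are polymorphic, fully ungapped columns. Per sequence
pair, sites score +1 (agree) / −(g+1) (disagree) with g=1 by default (the
penalty scale is the one free parameter; recovery and calibration tests
gate it). All maximal positive segments are extracted with the Ruzzo–Tompa
algorithm (verified against a quadratic restart-Kadane oracle);
significance is by permuting site order — Sawyer's null of site
independence — with the add-one permutation p-value, then Bonferroni across
pairs. Only inner (within-alignment) fragments are implemented; pairs with
no disagreeing site carry no contrast and are skipped.

## Neighbor joining and bootstrap

Classic Saitou–Nei agglomeration on the Q criterion. Ties in the Q
minimization are broken by the lexicographically lowest pair of subtree
labels (each internal node keyed by its smallest leaf label), making output
platform-independent. Negative branch lengths are clamped to zero with the
deficit transferred to the sibling edge, the standard repair. The final
three nodes join by the three-point formulas. On additive matrices the
output tree reproduces the input distances exactly (machine precision);
scikit-bio's independent NJ is used as a topology cross-check in tests.
Bootstrap resamples alignment columns (sites, not codons — the trees are
nucleotide p-distance trees), and supports are the percentage of replicates
containing each internal bipartition of the point tree. Rooting places the
root at the midpoint of the outgroup's pendant edge.

## Dating

`T = T_cal × k_obs/k_cal`, reported to one decimal with round-half-up
(35 × 4/22 = 6.3636… → 6.4). The calibration pair (`k_cal`, `T_cal`) is
always caller input. The 95% interval scales the exact (Garwood) Poisson
interval for `k_obs`; it is supplementary output, so the headline point
value is unchanged by it. Class-specific substitution counts use the same
pathway logic as the divergence module and are rounded half-up to integers
(multi-hit codons contribute fractional pathway-averaged counts).

## Synthetic generators

**CDS pairs.** One lineage evolves from a random CpG-depleted start CDS
(first-order chain with P(G|C) = 0.11, stop codons resampled) by a
Gillespie walk: per-site attempt rate 1, multiplied by `cpg_mult` while the
site sits in a CG dinucleotide (context re-evaluated at every event, across
codon boundaries, so CpGs can be created and destroyed), nonsynonymous
changes accepted at relative rate ω, stop-creating changes rejected. Branch
length `t` is in expected substitutions per neutral non-CpG site. Defaults
(315 codons, t = 0.09, ω = 0.9, cpg_mult = 20) emulate a young primate
paralog pair: ~45/315 codons CpG-flagged and synonymous divergence near
13% falling to ~8% under CpG exclusion. The truth record stores the event
log plus realized difference counts recounted from the emitted pair.

**Palindromic loci.** Arms are built from i.i.d. random units
(`arm1 + loop + revcomp(arm2)`, arm2 starting as a copy of arm1), then:
background point divergence on arm2; Poisson-count conversion tracts
(geometric lengths, mean 500 bp — no tract-length model is asserted by the
analyses, only recovery invariants) copying arm1 onto arm2 except inside
the protected island; island divergence applied last. The island is the
planted signal, so its mutation count is exact (`round(length × rate)`,
random positions) and the truth record carries a known planted divergence;
background and conversion remain stochastic. Defaults: 12-kb units, 3 units
per arm, 0.2% background, 8 tracts — arm identity ≥99% with a ~2% island,
the homogenized-arm regime. An optional outgroup arm (5% divergence) gives
conversion detection its "others differ" context. What the generator does
*not* emulate: indels, tandem unit turnover, segmental deletions, repeat
families — so passing tests demonstrate correctness of the estimators
under point-substitution structure, not robustness to structural noise.

**Family alignments.** Sites evolve i.i.d. down a caller-supplied tree
under Jukes–Cantor (per-branch change probability `(3/4)(1−e^{−4b/3})`,
uniform among the other three bases; exactly additive across branches).

All generators are deterministic given a seed, and truth recounts are
asserted against the emitted sequences in the test suite.

## Pipeline

`run_full_analysis` executes six stages — palindrome, units, armscan,
islands, conversion, divergence/dating — on user files or the synthetic
generators, writing TSV/BED/newick/JSON outputs and a manifest with
parameters and SHA-256 digests of every output; identical config + seed
give identical digests. Configuration is a dataclass, optionally loaded
from a YAML key-value file with unknown keys rejected. Defaults follow the
package's analysis conventions: 500-bp non-overlapping windows, spanning
CpG rule, pairwise deletion, 1000 bootstrap/permutation replicates.

## Problem sizes in the test suite

The suite exercises the statistical claims at sizes chosen to keep the
default run fast while leaving the estimators in their asymptotic regime:
island recovery over 50 seeded 10-kb-arm loci, detector calibration over
500 (island) and 200 (Sawyer, 400-site alignments, 1000 permutations) null
runs, the CpG contrast over 100 seeded 315-codon pairs, estimator/oracle
agreement over 1000 random ≤5-codon alignments, and NJ exactness over 100
random 5–8 taxon additive matrices.

## Known limitations

- No indel handling inside the estimators beyond deletion policies;
  alignments are trusted as given.
- Sawyer outer fragments (against external panels) and mosaic
  recombination mapping are out of scope.
- Maximum-likelihood codon models and rate-heterogeneity corrections are
  out of scope; Jukes–Cantor is the only multiple-hit correction.
- The island detector assumes a single background rate per arm pair;
  strong regional rate variation would miscalibrate the binomial variant
  (the permutation variant is the fallback).
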