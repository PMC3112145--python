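"""Exon-phase conservation across vertebrate gene models.

Walks the conserved coding-exon sizes of a vertebrate gene family through
the reading frame and compares the resulting phase profiles between
species.  Identical phase profiles across fish, frog and chicken argue for
one-to-one orthology of the single-copy genes.
"""

from palevol import compare_phase_profiles, exon_phases

# coding-exon sizes (bp) conserved from fish to mammals
SIZES = [64, 80, 95, 80, 43, 63, 115]

zebrafish = exon_phases(SIZES, initial_phase=0)
chicken = exon_phases(SIZES, initial_phase=0)
frog = exon_phases(SIZES, initial_phase=0)

print("exon sizes:", SIZES)
print("phase profile (start, end) per exon:", zebrafish)

report = compare_phase_profiles({"zebrafish": zebrafish, "frog": frog, "chicken": chicken})
print(f"shared exons: {report.n_shared}, conserved: {report.conserved}")
# each (s, e) pair is the codon phase entering/leaving the exon; e.g. the
# 43-bp exon starts in phase 1 and ends in phase 2 because 1 + 43 = 44 = 2 mod 3.
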