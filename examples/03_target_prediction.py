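"""Seeded Smith-Waterman target prediction on a single miRNA/UTR pair.

Shows the alignment a full-complement site produces, its score under the
seed-scaled scheme, and its duplex free energy under the shipped
nearest-neighbour model.
"""

from cncnet import ScoringScheme, sw_align_seeded, annotate_energy, reverse_complement

mirna = "UGAGGUAGUAGGUUGUAUAGUU"   # a classic 22-mer
utr = "AUGCAUGCAU" + reverse_complement(mirna) + "GCAUGCAUGC"

scheme = ScoringScheme()  # match +5, wobble +2, seed 2-8 x4, thresholds 140 / -20
sites = annotate_energy(sw_align_seeded(mirna, utr, scheme))

for aln in sites:
    print(f"site at UTR {aln.utr_start}-{aln.utr_end}, "
          f"miRNA {aln.mirna_start}-{aln.mirna_end}")
    print(f"  miRNA 3'->5': {aln.mirna_aln}")
    print(f"  UTR   5'->3': {aln.utr_aln}")
    print(f"  score = {aln.score:.0f} (threshold {scheme.score_threshold:.0f}), "
          f"dG = {aln.free_energy:.2f} kcal/mol (threshold {scheme.energy_threshold:.0f})")

print("\nA hit is kept only if BOTH thresholds pass: score >= 140 and dG <= -20.")
print("The seed (miRNA positions 2-8) is gapless and scores 4x; a full 22-mer")
print("complement therefore scores 15*5 + 7*5*4 = 215.")
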