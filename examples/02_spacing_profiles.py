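"""Spacing-distance profiles and the dinucleotide-shuffle null.

The distance L between two dinucleotides is the difference of their
start positions (L=1 intersected, L=2 adjacent, L=3 one spacer base,
L=4 two spacers).  UCNE-like sequences carry an excess of specific
pairs at L=4; a dinucleotide-preserving shuffle destroys that
arrangement while keeping all dinucleotide counts exactly, so the
shuffled profile is flat.

Here the TA..GC pattern (TAnnGC) is planted at 4 occurrences per kb and
its profile compared against shuffles of the very same sequences.
"""

from ucnescan import Motif, dinucleotide_shuffle, spacing_profile
from ucnescan.synthetic import spec_from_targets, markov_generate

spec = spec_from_targets(37.0, gpc_enrichment=1.5, ccgg_depletion=0.7,
                         planted_motifs=[(Motif("TAnnGC"), 4.0)])
seqs = markov_generate(spec, 80, seed=5)
shuffled = [dinucleotide_shuffle(s, i) for i, s in enumerate(seqs)]

prof = spacing_profile(seqs, "TA", "GC", lmax=8)
null = spacing_profile(shuffled, "TA", "GC", lmax=8)

print("L   planted freq   shuffled freq   shuffle band (mean +/- 3 SEM)")
for L in range(1, 9):
    lo, hi = null.band(L)
    flag = "  <-- excess" if prof.frequencies[L] > hi else ""
    print(f"{L}   {prof.frequencies[L]:.5f}        {null.frequencies[L]:.5f}"
          f"         [{lo:.5f}, {hi:.5f}]{flag}")

print("\nThe planted TA..GC signal stands out at L=4; shuffling the same "
      "sequences\nremoves it even though every dinucleotide count is "
      "preserved exactly.")
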