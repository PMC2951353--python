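# Opposing-arrangement lesion-plasmid architecture (pQTo-like toy construct).
# Both strands carry the T-T (6-4) photoproduct at the same position, so
# replicated copies can arise only by TLS or by deletion; the reference reads
# the undamaged top-strand sequence (TT) at the site.  Synthetic fixture
# geometry; the flanking sequence is arbitrary.
id: pqto-fixture
arrangement: opposing
reference: AATTGAGATGTGTTCCTTCTAACTTCCTGATAGCGCGGTCTTCTCCAGTCTCCTAGAGTTAACGAGGTGGAATTGACGAATATAATTCCG
top_site: [40, 42]
bottom_site: [40, 42]
marker: GC
accurate: AA
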