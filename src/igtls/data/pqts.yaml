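# Staggered-arrangement lesion-plasmid architecture (pQTs-like toy construct).
# The reference is the marker form: the top strand an error-free
# template-switch product reads, with the GC marker at both lesion sites.
# The two T-T (6-4) photoproduct sites are separated by 28 intervening
# nucleotides, as in the original construct.  Synthetic fixture geometry;
# the flanking sequence is arbitrary.
id: pqts-fixture
arrangement: staggered
reference: CGTAGCGCTCTCAACATACACACGACCAATGCGGACATCACAGCAATGACCATATCAGGAGCGAATGGTTTCTGCTCGAATGTACAAGCTCTTTATATTG
top_site: [30, 32]
bottom_site: [60, 62]
marker: GC
accurate: AA
spacer: 28
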