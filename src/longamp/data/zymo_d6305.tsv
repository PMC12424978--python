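taxon	genome_size	operon_copies
Listeria_monocytogenes	2992342	6
Pseudomonas_aeruginosa	6792330	4
Bacillus_subtilis	4045677	10
Escherichia_coli	4875441	7
Salmonella_enterica	4809318	7
Lactobacillus_fermentum	1905333	5
Enterococcus_faecalis	2845392	4
Staphylococcus_aureus	2730326	6
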