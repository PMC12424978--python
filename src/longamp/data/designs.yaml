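# Default amplicon designs. Primer sequences are the canonical Earth
# Microbiome / universal 16S primers; the long-operon ("StrainID-style")
# reverse primer is a configurable stand-in for the unpublished kit primer
# and binds ~550 bp into the 23S gene on the shipped synthetic scaffold.
designs:
  V1V3:
    forward: AGAGTTTGATCMTGGCTCAG   # 27F
    reverse: ATTACCGCGGCTGCTGG      # 534R
    min_length: 100
    max_length: 600
  V4:
    forward: GTGYCAGCMGCCGCGGTAA    # 515F
    reverse: GGACTACNVGGGTWTCTAAT   # 806R
    min_length: 100
    max_length: 600
  FULL16S:
    forward: AGAGTTTGATCMTGGCTCAG   # 27F
    reverse: GGTTACCTTGTTACGACTT    # 1492R
    min_length: 1200
    max_length: 1800
  STRAINID:
    forward: AGAGTTTGATCMTGGCTCAG   # 27F
    reverse: CGACAAGGAATTTCGCTACCT  # synthetic 23S reverse (assumption; override for real kits)
    min_length: 1000
    max_length: 3500
defaults:
  max_mismatch: 2
  terminal_exact: 3
  pairing_ceiling: 10000
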