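>SSU_scaffold synthetic rRNA scaffold with embedded primer motifs
AGAGTTTGATCATGGCTCAGCAGCTAGGGGGTTGTTGATATCAAATGAATTATACAGGGGCCCGACTATG
GAGGACCTCTCTGCAATACGCGAAAACCTTCGGTTCTGGCCGGCGCCAGCCTCCGAACCGATATCGTGAC
GGCCACGCTTGCCGGCCTATGGAATTTCACTGGCAGAGTAGTAACTGATCGGTTTAACCCCTAGCGTAAT
TGGTGATTCATCATCTCCGCTCCGAACGTTTTTTAGGAGATTCCGTCTGTGCCGGGGTCCAAATCCCTCT
CTTCATGCTGGTTAGGTACCTGATCCTTCAACTAGCGTATTCAATTGCCCTTGTCCTAGGCTCCTCGATG
GACTCCTCTCTTTGGCGTCTCCCGCGCGCTAATCCACGGGCCTGTGCGGGCGGTGGAGTGACGGTTCGAG
CCCTATATACACACTATTAGGTATGGAGCGAGCCCAGTATGCTGACATCAATTACCTACTGGTAGACCAT
TAGCTTAAACGACACCCGAGAGAATGTGCCAGCAGCCGCGGTAATTTAGGTGGCTGCGATGTTGCTGTGT
ACACTATGAGTTCGATGACGCCCCCTGTGACCGCCGATAAGTTAGGGTCGCAGCTTTACCCTTGCCCGTT
AAGCTGCAGTATGGGTAACACGGGGGGAGCGTTTATGTTTTTCGCTTGTCGTCCTGACTGTAGTGCCGTT
CATCCTCATTACAACATCAAGTCTCTTGATGACTATATTGTGAACTTAAACTGGACTACTCGTGGCGCCA
AGGGCCACAATGTCGATATTAGAAACCCGGGTAGTCCTATGATATGTCGATGCTTACGTCAGTTGCAGGG
TTCGCCAACAGATCAGATGGCGTTGGGTCGCTAGGGAACTATATGCTGCCCGCCGGCCACATCGGCTACT
CTCTTGCTCTAGTTAGTCTGGCCCTGTAATGGCCTGAGAAAAAGGCTTTAGGAACTAGCCGTCTTATTGT
ACGTTGAAGAGTGGCTTCACAAACAGAATACGTGACGACGGAGGCAACCTCATGAAGGGGGCGGTGTTGC
GGTATCGGTCTAAGTTTCACTTGCGTTCTAATTTTGGACCTAAGGTAAGAATAAAATAGTCTTTACGAGG
CCAAATTCCCAGGCTATCTCGTAAACGGGACGACAGCTGCCCATTCCTTGAAGCTACTTGGGATGTCTTG
TTACCACGGAGGTCGTTTGCGAGTATAGAGTCTCCAGGACCTCATAAAACGTCGGGTATCCTGGGTTCCT
ACAAAACCGTTTACATGCCGGGGTGAATTACGGTGTCGCAAGTGCTGGCTCCCGGCAGGCTGAGAGTCGG
GTTAGTCAAGAATTCCTACCCCGTCGCGGCTCTGAAAGACCAAATGGCCTTGTCTATCTGTCGTTCCTAT
GCATGAATGGCACCGCAAACAATGAAATGGTATGATGCGTTTTTCTGTCGAGCTGTCACCTCGTCTTTGG
CCCCGAATCGGCTTTCGTAACGGCAATACAGACGAACTGCCTGACACCCAAGTCGTAACAAGGTAACCTG
>LSU_scaffold synthetic rRNA scaffold with embedded primer motifs
ACTAGAGTGCTCAGCACTTGCTCATCATTGGCGCACAGACCGAGTCCTGGCATGTCAGTCGCGTAAGCCT
TACGCACGTCGAAACCTCGGCCCTTGGCAGAGCATATGGCTGCAAATCCCAAACCACAGTACGAGGGTCC
GTACGATGTCCATTAGAAATCGAGCTGGCACTCGGAGCTTACAGCTCCAAGGACATAAAATGAATATCCA
TACCGTTAGGCTGGTTCTCGCCGAGCCCTCTGGCGCTGAAACGACGCGTGCACTTGGTATTACATGAATC
CTACGTCCCGCGCATACTCGGTACATGTAAAGCGCTCACAGAATACCGCGTGCTGCCGCCGGTAGCAGCT
GGCGTCTCCTTGTGTTCCATTATCGCTCATGTAGACATGGGCACTGGTCCGTAGAATACTAATCTAGTCG
CACTTGGTTTAGCGACTAAAAGACTGCTTACGTTCAAGGATGCACACCCAGAAGTTATTACGTCATCAGG
TACTTAGGATAATCATTCGCGCTTCTTCGATCAGTTCAGAGGTAGCGAAATTCCTTGTCGTTGCATCATG
AGGTGCTCTACGGGTCATGTAGTGGCTGCGGCGCGTCTATTAGTATCTACAGATACAGTTTAACAAGCGC
TCAGAGTCAGGTCCTCTCAGCTGCAAGTAATTTGCCTGGTCCGAATATGGACACATCCCCAACAAAGGGG
TAAATTGCCCGTTCCCTTGGCGCGCATCACCCGGCGCGACTGGGCCATCGCACTGCGCAGACTTCGCAGA
CGTACCGCGTTGCTCATGCTCGCGAAAGGAGGGCCACGCGCGAGTGCTGGTATTGTGACTTGTGTAAGTC
GCGACGCCCTGGCAGAACCGATCACGTACGTATTGTGGCTACCACGCCGTATTAAGGGGT
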