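>L1rep synthetic example amplicon 3'-end window (not a real sequence)
GGAGTTTCCATCCCGTCAGCAAGGACAGTTTGTTTGACACCGAGCTTGACCTTGGACCTT
AAAGGCTCTGCGTGGTAGATCTAAGTGAACGGTCTTGCCCGGGGTAGGCAGAAACGGGAC
CAACTGACTAAGTGACGATGCACCGCGTACGGGCTATGACGGAAAGCCTTACTTAGGGCA
TTCGGCGTACCGTGTGACTTCGTAAACGTTACGGCGTAAGTCACGACCCGTATTAGTCAC
>GAPDH synthetic example amplicon 3'-end window (not a real sequence)
GGACAGCGGTGCTGTCGAAATTGGCGGAAAACAGAGGCACCTTCCGAAAAGCGCCCCTCA
CTTCGTAGTTGTCGGATTTAGCTCCAGAACAGGGCTCCCCCTCAAAAAGGTTGGCCACGA
TAGGATAAATTCCCGCTAGCTGACTGGAAAGCTCACGGGGGCCTACCCAATATGTACGTA
CACAGAATCACACGACGTGAGCTAGCCGACGTGGGTTACCTGCCGCGAAGAATCGGCAGG
>PABPC4 synthetic example amplicon 3'-end window (not a real sequence)
CTCGTGCAGTCAGTACTGCTATGGAGGAAGCTGAAAGAGCAGTTGATATTGATCGAGGTT
GAGCCTACCTTTTTTCCTTCAGCGAAAGCATAAACGATGAGCGTCGTCCCCCGACTTATA
ACTGCATTGTGAGTTTAATAGAGCACCGTTGAACCGAAGGGTCCATACGTGAGGCTCAGA
TCGCTCGCTGTGGCTATGAGCGAGGATAAGAGCGTTAGCAAAGCACATGGAGCTTGGTTG
>L1_consensus synthetic example amplicon 3'-end window (not a real sequence)
ATTTCCTTACCCGCACAATGCGTAGAGTGCATCGTCTCTTCTCTTCGTTCACTGCGTACC
CCTTGTCTAAGGATGCTAACATTGCAACCTCCTCATAACGGAACTAAAGCTATAGAAAAG
GTGACTCGATCCGCGGCAGTTCACATAACCCCACGAGAACACCACTGCGTCTCCAGAGCT
TTAGACTGATACTAGGGAATAAAAATATGGAGTACTCAGTATCCCCATATACGGTCATCA
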