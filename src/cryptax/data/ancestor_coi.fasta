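>ancestor_coi 557 nt reference used by the synthetic generator
AAACAAAGCGACGTAGCGTAAACAGTACGGACAGTCTTGTGATCGTGCCCATCAAGGATGCAGGCACGGA
GATATCCTCATAAGACCGGGATATCCAGATCGGTGCCGTCCTATCCCCTGTCATAAGTGAAAGAATACGT
GCTATAGCCTAATCATAATAAGTGTACCCACGTGAAGGTACGACCTCAGTGCCAAAAGTGCCGAGCTCCT
GTTAATATAACCGCCGTTATCGTTACTAAACTCCCGACGGCGGGAGAGGGACTACATTTCTCTGAACGAA
CAGCGAGGTGGGACCGGGACTAATGCCCTATTCCACTAATCCGCCGGGGGCGGGGGGTGTCGTAATGATT
CAAGTCTATGGTTGTTTTTTTAACAATAAACTAATGGGAAACGATGCCTCGCGAACTATCGTACAACAGG
CCTATAACATATTAGAATCCACGAATTCAGTTTCGTTTGACGTTGCAGTTACCGGCCCGCGGTGATCTAT
CTGACGTCCAGGCGCGTGGATCGACAAGAACGTTAACCAGGATGGTCTGGCCAAAGGTAAACAAGCG
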