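>HLA-E*01:01:01:01 synthetic toy promoter amplicon, NT-26 G
AGGGAGGGAAGAAATTCAATGACAATATTTGATATCGATTGCGGACGTGACCCGGAAGACCCTTCGAGCA
GGCTCGCATGCGGGAGTTAATAGGATCTAACGGCCTCTTTCGAAAGATTGGAGCTCGCCCCGGGCTTCCT
GAACTAGTCGGGCAAATTCAGAAAACGCATATTTAAAAAAGTGGCAGATACTCCAACCGCACCCTTACTT
TACGAACGAGAAGTTGCAAAAAGCGTACTATGAAGGCTGGCCCGCTTTTTACGGAATAACTGAGAAAGCG
AGGTTATGGATGCTTGAACACACCAACAGGCGTCACTGTGATTTAAGGGCGCTGCGGTGGGACATTATTG
CGAGCACAACACTCATGGCCGCACCCATATTAGTGTCACGTACATAGTGT
>HLA-E*01:01:01:06 synthetic toy promoter amplicon, NT-26 T
AGGGAGGGAAGAAATTCAATGACAATATTTGATATCGATTGCGGACGTGACCCGGAAGACCCTTCGAGCA
GGCTCGCATGCGGGAGTTAATAGGATCTAACGGCCTCTTTCGAAAGATTGGAGCTCGCCCCGGTCTTCCT
GAACTAGTCGGGCAAATTCAGAAAACGCATATTTAAAAAAGTGGCAGATACTCCAACCGCACCCTTACTT
TACGAACGAGAAGTTGCAAAAAGCGTACTATGAAGGCTGGCCCGCTTTTTACGGAATAACTGAGAAAGCG
AGGTTATGGATGCTTGAACACACCAACAGGCGTCACTGTGATTTAAGGGCGCTGCGGTGGGACATTATTG
CGAGCACAACACTCATGGCCGCACCCATATTAGTGTCACGTACATAGTGT
>HLA-E*01:03:01:01 synthetic toy promoter amplicon, NT-26 G, variant at column 57
AGGGAGGGAAGAAATTCAATGACAATATTTGATATCGATTGCGGACGTGACCCGGAAAACCCTTCGAGCA
GGCTCGCATGCGGGAGTTAATAGGATCTAACGGCCTCTTTCGAAAGATTGGAGCTCGCCCCGGGCTTCCT
GAACTAGTCGGGCAAATTCAGAAAACGCATATTTAAAAAAGTGGCAGATACTCCAACCGCACCCTTACTT
TACGAACGAGAAGTTGCAAAAAGCGTACTATGAAGGCTGGCCCGCTTTTTACGGAATAACTGAGAAAGCG
AGGTTATGGATGCTTGAACACACCAACAGGCGTCACTGTGATTTAAGGGCGCTGCGGTGGGACATTATTG
CGAGCACAACACTCATGGCCGCACCCATATTAGTGTCACGTACATAGTGT
>HLA-E*01:03:02:01 synthetic toy promoter amplicon, NT-26 G, variants at columns 57 and 310
AGGGAGGGAAGAAATTCAATGACAATATTTGATATCGATTGCGGACGTGACCCGGAAAACCCTTCGAGCA
GGCTCGCATGCGGGAGTTAATAGGATCTAACGGCCTCTTTCGAAAGATTGGAGCTCGCCCCGGGCTTCCT
GAACTAGTCGGGCAAATTCAGAAAACGCATATTTAAAAAAGTGGCAGATACTCCAACCGCACCCTTACTT
TACGAACGAGAAGTTGCAAAAAGCGTACTATGAAGGCTGGCCCGCTTTTTACGGAATAACTGAGAAAGCG
AGGTTATGGATGCTTGAACACACCAACAGGAGTCACTGTGATTTAAGGGCGCTGCGGTGGGACATTATTG
CGAGCACAACACTCATGGCCGCACCCATATTAGTGTCACGTACATAGTGT
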