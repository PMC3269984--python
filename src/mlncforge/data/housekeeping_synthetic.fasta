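>synthHK-tRNA-1 synthetic housekeeping ncRNA stand-in
TATATGGATTAAATACTGCTAAGGGATTAATCAAGCACCACGCCGACTCAGGCCAGTGTA
ATCCTACATAAGTAAG
>synthHK-tRNA-2 synthetic housekeeping ncRNA stand-in
GCATCATAGGAGCTTTCTCCCGTGGATATGATATTTTGAGATACTCGGGTAGTAATAGGT
GACCACAATCCACC
>synthHK-snoRNA-1 synthetic housekeeping ncRNA stand-in
TCGTCAAGCCACCAGGGTGGAGTCTAACATCATGCTGAGTCGCGGAGACTCTCCCGGTCT
ACCTACCTCCACCTAGAGGCCTCAAGCCGACGCTGCCTCCCCAGTCCAGTCAGCATCCAG
>synthHK-snoRNA-2 synthetic housekeeping ncRNA stand-in
ACCTCTCAAGTACGGCGTGGGGCAGATGATGTCTAGCGAAGTGTAGGACTCAGCATGATT
GATCTCCATCATTGTCCAGAGTTAGTGGTCGTGCCAAGCGTGAAATAAATAATAATATTC
TAACCGAAAACACCGGGACATAGAG
>synthHK-snoRNA-3 synthetic housekeeping ncRNA stand-in
GGGTCCCATCGTGTGGAAACGAGTCTCCGCGTCACTATCGTTCCGACCCGGGATCCCCAT
TCCGTGTAGTCCTAAGTAGGCTTAAGAACGTCTTCTGCGAAGATAGGCATCGTGCGTGGG
ATCGTCTTAACGGAGGCGACAGCGCCACTTGCCGCATCAATCAATACCATTTGTTAGGCT
>synthHK-snoRNA-4 synthetic housekeeping ncRNA stand-in
ATGTTCTGAAGTCTCTGTTCAATCACCGTTGTCCGGTAATCGAGATACAGCAATAGGAGC
GAATGTTACTAGCGTCCGTCTGTAAAGCGGCACCGACCGATTATA
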