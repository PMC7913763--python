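>synthetic_repeat_01
TGTCCATGTAAAGTAACCTTTACATGACGT
>synthetic_repeat_02
TGTTTCAATACGGATGAGAAATTCATCCGTACACAATGG
>synthetic_repeat_03
AGGGCATAACCCAGCCCGGGTTAAGGCAGC
>synthetic_repeat_04
AGCATCCGTAACGACGGTTACGGAGTCCA
>synthetic_repeat_05
CGGTCCATTTATGGCACGATAAATGTCCCTT
>synthetic_repeat_06
GCTCCGGATGACACAACGTGTCATCCCCATC
>synthetic_repeat_07
GTGGAAGGTTTATTGGTTTTCAATAAACCTGTCGA
>synthetic_repeat_08
GGGTAAGGGACCAGCCAGGCAAGGCTGGTTGCTAAATGC
>synthetic_repeat_09
AACGACTGCGAGAACATCGCAGTCGTTC
>synthetic_repeat_10
GTTGACCGTGTGCGACTGGAGAGTCGCAGCGAGATCCC
>synthetic_repeat_11
AAGATTGGAAGATAAACTAGTTTATCTTCGATCATC
>synthetic_repeat_12
GCCAGTGAACAGACCAGTGTTCACTCTAT
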