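marker	gene	forward	reverse
MarVer1	12S	CGTGCCAGCCACCGCG	GGGTATCTAATCCYAGTTTG
MarVer3	16S	AGACGAGAAGACCCTRTG	GGATTGCGCTGTTATCCC
MiFishU	12S	GCCGGTAAAACTCGTGCCAGC	CATAGTGGGGTATCTAATCCCAGTTTG
Ceph16S	16S	GACGAGAAGACCCTAWTGAGCT	AAATTACGCTGTTATCCCT
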