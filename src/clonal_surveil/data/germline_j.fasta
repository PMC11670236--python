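>JH1
CGTCTGCAAGATGTTGGT
>JH2
TGTGATAATGTTGATGAT
>JH3
CATGCTCAATGGAATTGG
>JH4
GATGATCGTTGTCAAATG
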