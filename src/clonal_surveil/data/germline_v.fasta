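>VH1-72 cdr1_aa_start=26 cdr1_aa_len=8
AATATGGCTCCTACTACTTATATTATTTTTTATCTGCATCATCCTTATCATGCTCAACAT
GAATGTCAACGTTGTAAATTTATGTGGTATTCTCAATGGGTTGTTCAAGATCTGGAAGGT
ATTCAAGAAAATGGTGTTGTTCGTGCTCATATTACTGTTCCTATGGAAGGTGGTACTACT
TTTGATTGTATGAATCTGTATATTTATCAACTGCGTTCTCCTCAATGGGATCGTGCTGTT
AAATGGGCTGAAAATGTTAATTGTTGTAAAAATCCTTCTGGTTATGTTCGTCAT
>VH1-26 cdr1_aa_start=26 cdr1_aa_len=8
ATTCATATGAATCCTATGGTTTGTATGCAAATTGAAAATTTTGATTGTAAACGTAATATG
TTTATTAAAGCTTGTATTTGGCGTTGTCATGTTGATGCTCGTTGGATGGAAATTCAAGCT
TGGCCTAAAGAAGGTATTCCTGGTCGTTATTTTAAAATGAATAATAAATGGGATTATATG
TGTCTGCCTATGTGTGATGCTAATCATATTTCTTATTGTATTTATACTGATCAACCTCAA
CTGTTTTATGTTGGTATGATGCATCGTTCTTTTCATAAACCTACTATGTATAAT
>VH2-2 cdr1_aa_start=26 cdr1_aa_len=8
GATATTTGGTGGATTATGTATTTTGCTTGTGGTATGACTTCTGAACTGCGTATGCATCGT
TATTTTTTTCCTTGGCTGTTTGGTCCTGATAAAATTATTCCTGTTGATTGGACTGCTAAT
TATCTGGATAAACGTCCTGAAATTTTTCCTCATAATATGACTCAAAAATCTCCTTATCAT
AATTGTGCTGCTTGGACTCGTCAACATATGCCTGATGAAGCTTGTAAATTTCAAGCTCAA
CCTCATGATATTCATACTTCTCTGCTGCAAGAAGCTGAAGATCAACATCGTATT
>VH3-6 cdr1_aa_start=26 cdr1_aa_len=8
CATCATAAATATCATTGTAAATGGTGGGGTCCTGTTGAACAATATTATAATACTAAACAA
CCTTTTACTTATTCTGATCGTCTGTCTGGTAAAGCTAATTGTGAAGGTTTTATGCGTATG
CTGTATCTGATTGGTCTGCTGTGGCTGGAAGAAGATGATGCTCAAAATACTTATCGTCCT
CATAAAGATGGTCAAGATTCTGATCAACCTTTTACTTGTGATGCTTCTTATAAAAAAATT
CGTAAATATGCTCAAATTGTTAATGATATTGTTCAACCTGCTTGTTGTATGCAT
>VH5-17 cdr1_aa_start=26 cdr1_aa_len=8
TCTCTGGAAATTATGCCTATGCGTCGTCATCTGACTGAACATCTGCTGGCTGCTTCTGAT
TATCAATATGCTAAAATGACTGAACTGTGTATTGAACAAGCTGATGTTATTGAAAAATTT
GGTATGGCTGGTCGTTGGATGGCTCAAGGTTATTTTCAAATTAAACAATTTCTGCCTTCT
CGTCGTCCTTCTTGGGATCATCTGTGGCAAATTCATCCTATTATGTGTGATAATTTTGAA
ACTATTCAACGTCTGGATCCTATGCATTATGGTATGGTTCCTGGTTTTCCTTCT
>VH6-3 cdr1_aa_start=26 cdr1_aa_len=8
ATTGCTCAATGGGCTATTTCTCGTGGTTGGTGTACTCAACGTGCTCAACCTTGTGATATG
CATACTATGGAATGTGAACAATTTCGTCATGATCCTTCTTCTATGTGTTGGGCTTATTGG
ATGTGTACTCATCGTGATCGTCAATATTCTCCTTGTCAAATTAAAACTGATGGTCTGACT
GTTACTACTACTACTCTGCATTATGTTCTGTTTCGTCTGAATTTTGCTTGTCAAAAAGAA
TCTGATTGTTGTCATATGTTTGTTCAATGTATGAAACAATGGCATCGTTCTATT
>VH7-3 cdr1_aa_start=26 cdr1_aa_len=8
CTGATTATTAAACCTTTTCATACTACTGATTATGAAGATCATTCTCAAATTGCTTCTACT
CGTACTAATGATATGTCTACTTCTGATGAATATGAACCTGAACCTATTTTTATTAAACCT
TATGTTCAAGAATGTCATCTGCAATTTGATCGTCCTCCTTCTCATATTGAATATTTTATT
CCTTATCGTTTTCCTATGATTGTTCATTTTCAATTTGTTCATCGTAAAGTTATTCAAGGT
TGGCCTTGGAATCGTCTGACTTTTACTATGTGTCAAATTCCTTGTCCTAATGAT
>VH9-1 cdr1_aa_start=26 cdr1_aa_len=8
TCTTGTGAAATGGAACGTGGTCGTGTTACTTTTCCTATTGAAGCTGCTCCTATTTGTAAA
TGTTCTCCTATGGCTATGATTTGGTATATGCCTTATGTTCAAGCTTGGTGGTGGCTGCAT
TATTATGCTCTGCTGCATATGATTGCTCTGTGTTGTTATATGCATATGGTTGATAATGAA
CGTGTTCAAAAAGCTACTCTGCCTTGGATTGTTAAAACTACTGGTACTGGTTCTTATCAT
AATGTTTCTGGTGCTATTACTCGTAAACAATGGGAAGGTATTAAACATACTGTT
>VH10-1 cdr1_aa_start=26 cdr1_aa_len=8
ATGTATGGTTCTTTTTGTCGTCCTTTTGTTCCTCATACTTTTGAAGGTGCTACTTATATG
CATGAAGATGGTGGTTCTCATCATACTGGTGAATGGGAAGATCTGCGTCGTTTTTGTCTG
TATTGTTTTTGTCGTGGTTCTGAATATTGTAATTGTTTTGATTTTCAAATGTCTCAATGT
CATTGGCTGAATGATTGGCTGCATATGAAACCTCAAATTGAAATGGTTGTTCATGATAAA
GAAGTTGATGCTAAAGGTCTGCATGAACATCGTTTTCAAGCTGATCTGTGTCAT
>VH14-2 cdr1_aa_start=26 cdr1_aa_len=8
CATGATCTGGTTCAACTGCAATGGCTGTGGAAACTGGCTAATTGTCGTCTGTGGGTTTGG
TGTATGGAAATTTCTAATGCTGTTTTTGGTTGGTTTCAAATGCCTGAATGTTATGCTGCT
GCTGCTTGTTATGCTACTCAAATGGAAATGGTTGAAATTTCTGGTTGTATGGTTGATGTT
AAAGGTATTCTGTGTTATTTTTCTTTTCTGCCTCAAACTCATTTTTGGATTTTTCTGATG
ACTCCTGAAACTGAAAATGCTGTTCATCATCTGTGTAAAATGGGTTCTCAAGTT
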