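>synthetic-16S-target length=905 synthetic stand-in for the mitochondrial 16S rRNA benchmark target
GTGCTTAGATGTTATAAATTCGGATTATAATATTATGTTCAAAGTAAAAGGTTGGTTTAGATATGTATAG
AAAGATTGGTTTATAATATTTCTAATCTGTACTAAGGAATCAAATGGTAATAATCCAATTCAAGGATATA
ATAATATTAAACTTGAACGCAGGTGGTAACCTAATCATTGTGAAAAGGAGGTTTATTGATATTAAATTTA
AATTTAAGGATAAGTTAATTATTAGTATAGTTTAAGGTACTTTGGTAAAGATAAAAAAATTTTGGATAAT
TAAATAATTTATGATCTCTTGGGTCTTTAAATTATTTAATCATTTGGTTGGTTTTAAAAAAGAAATTTAT
TGGTTCTGGTCATTATTTAGTTTGAAAATATTTATGGATTATTGGTAAGAGTATAATATATTTGGAATAA
ATTCTATCCTAAAAAAAATTTGGTTAAAAACTGACTGCAATTCATATAGTAAAAAATTATCTTCTATACT
TTTTTTGGGAAAACCCAGTTGGTTTAAAAAAATCTGGCAATTAGTTATCTTGGTAGATATTTTGGAGAGT
TGTTTTTCAAGATGTTCTAATGGACTTTGAATCTGATAAACTTACTGTAGGAGTCATTAAAAAATCAAAA
ATTATGTGGTCATTATTTATTATTACATCACAACAGGATAATCTAGACATTTACATGTTAACTGGAAAGA
ATTAGTTAAATATTGGTTAAAGGGATTGGTAGTTATTATATTAAGCTTAGGTTCATCAATATAATTTCAA
TTGCGTTGGTACTCATTTTATGAAGGATTAAAGCTGGAATAATGTTATTTAAGCTGCTAAGTCGGACATA
GTAATATATCGAGTATTTTTAGGATTTTCGCTTATAGAATAGTGAAATAGGTTATTATAAATTTA
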