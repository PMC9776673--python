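>FLT3_exon14_15_amplicon synthetic stand-in sequence; coordinates hg19 chr13:28608108-28608315 (plus strand)
GGGTGCAAAACATAGGCATTCTATGGGCGCCAGTATTGGATCTGAGAAGCCGCGCAAAGA
GCCAACTTTTTACCTCGCTGCGCCACGACGTTCGACCTAGCAATGGGGCGCGTTCGTCAG
ATGAGTGCTCCTAGCTTTAGTGTTAGGGATATCGCGCTTTATTTCGCAGGTCAGTCGTAC
CCCCCTTCAGGTACGCAACTCTGCTCCA
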