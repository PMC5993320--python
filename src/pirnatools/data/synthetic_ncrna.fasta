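>rRNA_frag_01 synthetic contaminant reference
AATCGCTACATACTGGCGAGTAGTACCTACCAAGTCTGTTACGATGGCTTGAATCCACAG
CTTATCGAATTCGGTCGTCACCTTAAATTGTCGTACTACCAGCAGCCAATCCCGTTGGAG
ACGGTCCTATCATGGACACGACCGGATGTCT
>rRNA_frag_02 synthetic contaminant reference
TGGACCCGTCGCACGACCTGTCTGACGCAGATGAAACATGTTAGATCGTTCGTGAGAAAC
CCACGCTGCGACGCGATACTCCCTACGCCTAATGTGCAACACTCATGGGGGCAGTGAAGT
CCCTCATGGTTCGAACT
>rRNA_frag_03 synthetic contaminant reference
AGCACCCAATAAGATCTCGGGTAGGCTCGAGATCCACGATTTTGGCCGGGCCGTCTACTA
CTAAGTAACTCCTCTACTCCCGCTACACCCAGCGACGCACGGGAATCTACCCAGTTCCGG
TATGAACCTTCCGAGACCCCCTTCGCTT
>rRNA_frag_04 synthetic contaminant reference
GCATTAAAGCTTGTCATCACCCGCTTTGTATGCATGATCTACTGTCGCTTGGGAGATATT
TGCCCAGCCGTATAAGCCAGGATTCATTCTCCATCCCTCGCTCCTGTCTTTCAAGTAGTC
TAAGAGG
>rRNA_frag_05 synthetic contaminant reference
TAGCGCAGCCTACTTTGAGGCCTTTGATTCAGTACAAACTATTCGTTTCCAACACGGGCG
GGTCGTGGGCCCCAACTTTTAAAAACCATTTAAAATTCCCTAGCATTTAAAGCCTAACAC
CCGACTAAGAACGGCTTGCAAGTCTTTCCCGAAA
>rRNA_frag_06 synthetic contaminant reference
CTCCTCAGCGACAAGCGGCGTGATTGCGAAATTAACGCACGGTGTCTCTTAATCTTTGTC
GCTATATGCCCTTAACGCTGGACCTGGGTAGGGTCCCGCAGCACATGGGGCTGACCCTCC
GCAATGTAAAGGCGATCGCTTTTGACGAAG
>tRNA_01 synthetic contaminant reference
CCGTCTCCCGATACAGCGCGGGCCTGCACATAGATGGGTATTGCGTCTATGTAAGCCGCG
AAGCCTCTCGTCTATGCTCATG
>tRNA_02 synthetic contaminant reference
TGAGACCACTGTACTCTGGACCGGTCTTTGACGCACTTGAGATACGAATCTCACCCTGCC
AGATTGGGGTGCGCCGGGCCTATG
>tRNA_03 synthetic contaminant reference
CGGTAACTCACAATTGGAAAAAGGAAAATGACCAGATGATAACGCCTGGACTGGCGAACT
ACGCTATGTACAATGC
>tRNA_04 synthetic contaminant reference
TGAAACACTACAGGACTGGTTCGCGCATTAATCCTGATATCACATGAAATCCCTAGAGCG
GCAAAACTTTCTGTCACGGGTA
>tRNA_05 synthetic contaminant reference
GGTAGCACTTCCCTGTTCACATAATGAACCCAATTCCGTCGGAGGGCGCTAGAATAGACG
CCACCTTAGAGCAGTCGCGTCTGCCGTCA
>tRNA_06 synthetic contaminant reference
ACTCCATTAGTTATAAAGCTATATTTAAAGAATCCGGGTCGCAAAAACTTTGCTGTCTCA
TATTGCGGCCCGTAGAGCT
>snRNA_01 synthetic contaminant reference
ACTGCGACTGTTCAAAAAACGGCTGTCCTTCCAATATCATTGTCGGGTACCGATCGATAC
AGGCGATTACCTATTGGCACGGCCGTCTAAGGGTTACTAAATAGGACTTGTGTTTTTATA
C
>snRNA_02 synthetic contaminant reference
AGAGGCTGGTAGCGTGATGTAGCTCCGAAAGTACCTCAAGGGTAACCACCCCAACACATC
ACGTTCTCGGAACTGTTCTTCGAATCGCAGGAAGATGTACAAGCGTATTCCGTATACAGC
GTGTGG
>snRNA_03 synthetic contaminant reference
CCTGCGCTATGAAGCACGTCCGCCCCGGACTTGTCTTCAGACAGCTACGTAAGGAGACGA
ACGCAGCACGAAGATATGATTCCAAAATCTATGTTTCGCGATTTGTTAAAAAC
>snRNA_04 synthetic contaminant reference
ATCGCAGCGGGCGGTGTGCTTAGAGTTTTTCATATGGAAGTACCTCGACCTCATACAAGT
AAGGGCACTGTTCAAAATTCTGCAACACGCGGCGCCACCATCGTAGGACGACAACTGCGA
TACGAGT
>miRNA_hairpin_01 synthetic contaminant reference
CACGTAATGTTAACCACTTTGCGGAAGATACGGGACGTTGATTCATGTACGCAACCTATT
TCTCTCGCATCACTGCCACTCAACCATGTGTTTGAACCAGCACCAATT
>miRNA_hairpin_02 synthetic contaminant reference
TGGTATCAACATATTTTAAGATTGGAACTCACAGTCGTCAGTCGCGCTGGCCCTCAATCG
CGCCGCGGGTAAGATAACCGTAGGTTCTAAA
>miRNA_hairpin_03 synthetic contaminant reference
CGCTGAGGTTCTTTTCCGAGCGGTTCACAGTCAATCGCCAACGGGGGACGTTACCCCATC
TTATTTGCGTTTGGTAAGCGGCGAAATGATTGGTCCTT
>miRNA_hairpin_04 synthetic contaminant reference
ATTCATTTCGATTTGACAGTTCAAACGTCGAGTGTATTTACCCTGCATCAAGAACGGTGA
GTCGGCATTATCGTTTCGGTGCCCCTCGCATTTTGGCAG
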