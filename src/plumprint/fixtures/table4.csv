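locus,forward_primer,reverse_primer,dye,annealing_temp_c,reference
UDP98-407,AGCGGCAGGCTAAATATCAA,AATCGCCGATCAAAGCAAC,HEX,58,Cipriani et al.
PacA33,TCAGTCTCATCCTGCATACG,CATGTGGCTCAAGGATCAAA,ATTO550,58,Decroocq et al.
CPSCT026,TCTCACACGCTTTCGTCAAC,AAAAAGCCAAAAGGGGTTGT,6-FAM,46,Mnejja et al.
BPPCT040,ATGAGGACGTGTCTGAATGG,AGCCAAACCCCTCTTATACG,6-FAM,58,Dirlewanger et al.
BPPCT007,TCATTGCTCGTCATCAGC,CAGATTTCTGAAGTTAGCGGTA,HEX,60,Dirlewanger et al.
BPPCT034,CTACCTGAAATAAGCAGAGCCAT,CAATGGAGAATGGGGTGC,6-FAM,56,Dirlewanger et al.
UDP96-005,GTAACGCTCGCTACCACAAA,CCTGCATATCACCACCCAG,HEX,56,Cipriani et al.
BPPCT039,ATTACGTACCCTAAAGCTTCTGC,GATGTCATGAAGATTGGAGAGG,HEX,58,Dirlewanger et al.
BPPCT014,TTGTCTGCCTCTCATCTTAACC,CATCGCAGAGAACTGAGAGC,6-FAM,58,Dirlewanger et al.
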