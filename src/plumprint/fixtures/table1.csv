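locus,group,size_min,size_max,allele_number,ho,pic,max_alleles
BPPCT040,LT-origin,115,155,21,1.00,0.274,6
BPPCT034,LT-origin,216,258,17,1.00,0.256,6
BPPCT039,LT-origin,126,171,15,1.00,0.286,5
BPPCT014,LT-origin,185,225,12,0.71,0.243,5
UDP98-407,LT-origin,168,197,11,0.71,0.258,3
PacA33,LT-origin,175,213,13,0.79,0.265,6
BPPCT007,LT-origin,124,161,14,1.00,0.374,6
CPSCT026,LT-origin,166,213,18,1.00,0.280,6
UDP96-005,LT-origin,96,154,19,0.71,0.240,6
BPPCT040,R-Plum,116,147,8,1.00,0.410,5
BPPCT034,R-Plum,216,258,13,1.00,0.308,4
BPPCT039,R-Plum,126,177,13,1.00,0.368,5
BPPCT014,R-Plum,185,225,9,1.00,0.358,5
UDP98-407,R-Plum,164,194,6,0.33,0.343,3
PacA33,R-Plum,168,210,11,1.00,0.333,4
BPPCT007,R-Plum,124,149,11,1.00,0.369,6
CPSCT026,R-Plum,166,210,13,1.00,0.368,3
UDP96-005,R-Plum,104,152,11,0.83,0.414,5
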