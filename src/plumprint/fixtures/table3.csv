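locus,group,size_min,size_max,allele_number,ho,pic
BPPCT040,hybrid,115,155,26,1.00,0.253
BPPCT034,hybrid,216,256,22,1.00,0.221
BPPCT039,hybrid,124,177,23,1.00,0.251
BPPCT014,hybrid,185,225,14,0.95,0.225
UDP98-407,hybrid,164,225,17,0.80,0.179
PacA33,hybrid,168,221,26,0.82,0.157
BPPCT007,hybrid,124,161,18,1.00,0.279
CPSCT026,hybrid,166,211,20,1.00,0.260
UDP96-005,hybrid,96,154,25,0.77,0.179
BPPCT040,parent,117,155,17,1.00,0.333
BPPCT034,parent,216,250,15,1.00,0.352
BPPCT039,parent,126,177,13,1.00,0.363
BPPCT014,parent,185,221,9,1.00,0.284
UDP98-407,parent,164,198,9,0.50,0.358
PacA33,parent,168,194,8,0.83,0.347
BPPCT007,parent,124,161,12,1.00,0.352
CPSCT026,parent,166,211,13,1.00,0.333
UDP96-005,parent,96,154,13,0.83,0.355
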