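locus,allele_size,category,freq_pct,printed_rare
BPPCT040,116,common,20,0
BPPCT040,120,common,25,0
BPPCT040,124,common,35,0
BPPCT040,126,common,50,0
BPPCT040,128,common,50,0
BPPCT040,134,common,30,0
BPPCT040,145,common,25,0
BPPCT040,147,common,40,0
BPPCT040,115,unique_lt,5,1
BPPCT040,118,unique_lt,5,1
BPPCT040,119,unique_lt,5,1
BPPCT040,131,unique_lt,5,1
BPPCT040,136,unique_lt,10,1
BPPCT040,138,unique_lt,5,1
BPPCT040,140,unique_lt,10,1
BPPCT040,141,unique_lt,5,1
BPPCT040,144,unique_lt,10,1
BPPCT040,149,unique_lt,5,1
BPPCT040,150,unique_lt,5,1
BPPCT040,153,unique_lt,15,0
BPPCT040,155,unique_lt,15,0
BPPCT034,216,common,75,0
BPPCT034,226,common,25,0
BPPCT034,229,common,10,1
BPPCT034,235,common,20,0
BPPCT034,236,common,15,0
BPPCT034,238,common,10,1
BPPCT034,241,common,55,0
BPPCT034,243,common,20,0
BPPCT034,250,common,15,0
BPPCT034,258,common,15,0
BPPCT034,222,unique_lt,10,1
BPPCT034,227,unique_lt,5,1
BPPCT034,232,unique_lt,5,1
BPPCT034,234,unique_lt,35,0
BPPCT034,237,unique_lt,5,1
BPPCT034,246,unique_lt,10,1
BPPCT034,247,unique_lt,5,1
BPPCT034,225,unique_ref,5,1
BPPCT034,249,unique_ref,5,1
BPPCT034,256,unique_ref,5,1
BPPCT039,126,common,35,0
BPPCT039,129,common,20,0
BPPCT039,131,common,15,0
BPPCT039,132,common,30,0
BPPCT039,136,common,25,0
BPPCT039,143,common,25,0
BPPCT039,145,common,15,0
BPPCT039,150,common,15,0
BPPCT039,153,common,70,0
BPPCT039,171,common,25,0
BPPCT039,128,unique_lt,10,1
BPPCT039,130,unique_lt,10,1
BPPCT039,141,unique_lt,10,1
BPPCT039,163,unique_lt,5,1
BPPCT039,167,unique_lt,10,1
BPPCT039,139,unique_ref,5,1
BPPCT039,159,unique_ref,5,1
BPPCT039,177,unique_ref,10,1
BPPCT014,185,common,85,0
BPPCT014,202,common,20,0
BPPCT014,204,common,45,0
BPPCT014,214,common,15,0
BPPCT014,215,common,20,0
BPPCT014,216,common,15,0
BPPCT014,218,common,10,1
BPPCT014,223,common,10,1
BPPCT014,225,common,25,0
BPPCT014,203,unique_lt,15,0
BPPCT014,208,unique_lt,5,1
BPPCT014,221,unique_lt,5,1
UDP98-407,181,common,30,0
UDP98-407,187,common,25,0
UDP98-407,194,common,20,0
UDP98-407,168,unique_lt,10,1
UDP98-407,172,unique_lt,5,1
UDP98-407,179,unique_lt,25,1
UDP98-407,186,unique_lt,5,1
UDP98-407,189,unique_lt,5,1
UDP98-407,191,unique_lt,15,0
UDP98-407,193,unique_lt,15,0
UDP98-407,197,unique_lt,5,1
UDP98-407,164,unique_ref,5,1
UDP98-407,177,unique_ref,5,1
UDP98-407,185,unique_ref,5,1
PacA33,175,common,50,0
PacA33,177,common,15,0
PacA33,185,common,30,0
PacA33,193,common,15,0
PacA33,194,common,30,0
PacA33,196,common,10,0
PacA33,209,common,10,1
PacA33,179,unique_lt,10,1
PacA33,183,unique_lt,20,0
PacA33,191,unique_lt,15,0
PacA33,192,unique_lt,5,1
PacA33,202,unique_lt,5,1
PacA33,213,unique_lt,10,1
PacA33,168,unique_ref,5,1
PacA33,198,unique_ref,5,1
PacA33,206,unique_ref,5,1
PacA33,210,unique_ref,5,1
BPPCT007,124,common,40,0
BPPCT007,126,common,20,0
BPPCT007,128,common,40,0
BPPCT007,130,common,55,0
BPPCT007,134,common,60,0
BPPCT007,136,common,20,0
BPPCT007,138,common,45,0
BPPCT007,140,common,50,0
BPPCT007,142,common,20,0
BPPCT007,144,common,10,1
BPPCT007,149,common,60,0
BPPCT007,134,unique_lt,10,1
BPPCT007,146,unique_lt,10,1
BPPCT007,151,unique_lt,30,0
BPPCT007,161,unique_lt,5,1
CPSCT026,166,common,55,0
CPSCT026,175,common,25,0
CPSCT026,183,common,25,0
CPSCT026,188,common,10,1
CPSCT026,189,common,80,0
CPSCT026,193,common,35,0
CPSCT026,196,common,25,0
CPSCT026,199,common,35,0
CPSCT026,200,common,20,0
CPSCT026,202,common,55,0
CPSCT026,204,common,25,0
CPSCT026,210,common,15,0
CPSCT026,173,unique_lt,5,1
CPSCT026,195,unique_lt,15,0
CPSCT026,197,unique_lt,15,0
CPSCT026,208,unique_lt,5,1
CPSCT026,211,unique_lt,5,1
CPSCT026,213,unique_lt,5,1
CPSCT026,185,unique_ref,5,1
UDP96-005,104,common,25,0
UDP96-005,105,common,10,1
UDP96-005,107,common,20,0
UDP96-005,112,common,30,0
UDP96-005,115,common,20,0
UDP96-005,125,common,15,0
UDP96-005,137,common,15,0
UDP96-005,148,common,35,0
UDP96-005,152,common,30,0
UDP96-005,96,unique_lt,10,1
UDP96-005,120,unique_lt,10,1
UDP96-005,124,unique_lt,10,1
UDP96-005,128,unique_lt,5,1
UDP96-005,130,unique_lt,10,1
UDP96-005,132,unique_lt,5,1
UDP96-005,134,unique_lt,5,1
UDP96-005,139,unique_lt,10,1
UDP96-005,142,unique_lt,10,1
UDP96-005,154,unique_lt,15,0
UDP96-005,127,unique_ref,5,1
UDP96-005,150,unique_ref,10,1
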