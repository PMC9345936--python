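phenotype,n,ntprobnp_median_pct_uln
A,13,208
B,15,141
C,3,809
D,4,1980
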