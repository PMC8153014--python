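dataset,OA
S2,89.83
S2+,91.03
S1,70.95
S1+,78.02
S2+S1+,92.88
S2+S1+DEM,94.30
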