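dataset_a,dataset_b,statistic,p_printed
S2,S2+,8.4767,0.0036
S2,S1,1387.7,0.0000
S2,S1+,288.21,0.0000
S2,S2+S1+,53.125,0.0000
S2,S2+S1+DEM,72.755,0.0000
S2+,S1,1429.7,0.0000
S2+,S1+,334.89,0.0000
S2+,S2+S1+,29.009,0.0000
S2+,S2+S1+DEM,47.617,0.0000
S1,S1+,987.85,0.0000
S1,S2+S1+,1516.9,0.0000
S1,S2+S1+DEM,1541.4,0.0000
S1+,S2+S1+,426.97,0.0000
S1+,S2+S1+DEM,440.41,0.0000
S2+S1+,S2+S1+DEM,4.0635,0.0438
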