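class,training_pixels,test_points
mangrove swamp,1862,265
mixed swamp,5727,589
palm swamp,1312,334
bog plain,3479,269
natural forest,11738,115
sparse vegetation,301,242
coconut,1350,282
rubber,1734,228
oil palm,656,70
built-up,1215,258
bare surface,101,172
water,18195,87
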