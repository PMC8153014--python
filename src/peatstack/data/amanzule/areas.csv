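class,area_ha
mangrove swamp,1633.78
mixed swamp,48851.29
palm swamp,5143.97
bog plain,4558.00
natural forest,102728.14
sparse vegetation,41856.35
coconut,18109.00
rubber,29998.06
oil palm,2606.22
built-up,5273.31
bare surface,90.25
water,323878.13
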