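class,dataset,UA,PA
mangrove swamp,S2,99.6,85.3
mangrove swamp,S2+,100.0,91.3
mangrove swamp,S1,74.2,74.7
mangrove swamp,S1+,85.0,72.5
mangrove swamp,S2+S1+,100.0,92.5
mangrove swamp,S2+S1+DEM,100.0,96.2
mixed swamp,S2,88.8,99.5
mixed swamp,S2+,91.9,99.5
mixed swamp,S1,82.4,73.7
mixed swamp,S1+,78.7,85.0
mixed swamp,S2+S1+,91.1,99.5
mixed swamp,S2+S1+DEM,92.3,99.7
palm swamp,S2,98.2,99.1
palm swamp,S2+,98.5,98.8
palm swamp,S1,85.0,91.9
palm swamp,S1+,89.4,95.8
palm swamp,S2+S1+,98.8,99.4
palm swamp,S2+S1+DEM,99.4,99.4
bog plain,S2,88.3,98.1
bog plain,S2+,91.3,97.8
bog plain,S1,78.0,97.4
bog plain,S1+,87.4,97.8
bog plain,S2+S1+,96.0,97.4
bog plain,S2+S1+DEM,95.0,98.1
natural forest,S2,60.8,95.7
natural forest,S2+,62.4,96.5
natural forest,S1,18.9,90.4
natural forest,S1+,33.2,96.5
natural forest,S2+S1+,66.5,98.3
natural forest,S2+S1+DEM,80.3,99.1
sparse vegetation,S2,92.1,81.4
sparse vegetation,S2+,93.5,83.1
sparse vegetation,S1,98.9,36.4
sparse vegetation,S1+,100.0,45.0
sparse vegetation,S2+S1+,93.6,90.9
sparse vegetation,S2+S1+DEM,94.8,90.9
coconut,S2,88.6,60.6
coconut,S2+,88.8,64.9
coconut,S1,78.6,46.8
coconut,S1+,83.2,51.1
coconut,S2+S1+,90.2,65.3
coconut,S2+S1+DEM,90.9,70.9
rubber,S2,94.3,86.8
rubber,S2+,92.2,88.2
rubber,S1,87.4,63.6
rubber,S1+,64.0,76.3
rubber,S2+S1+,94.0,89.9
rubber,S2+S1+DEM,94.4,95.2
oil palm,S2,88.4,87.1
oil palm,S2+,91.4,91.4
oil palm,S1,75.0,64.3
oil palm,S1+,79.7,78.6
oil palm,S2+S1+,98.5,94.3
oil palm,S2+S1+DEM,100.0,95.7
built-up,S2,87.6,88.0
built-up,S2+,87.6,87.6
built-up,S1,81.5,57.3
built-up,S1+,88.0,67.2
built-up,S2+S1+,90.6,96.5
built-up,S2+S1+DEM,90.5,95.7
bare surface,S2,96.9,91.3
bare surface,S2+,100.0,90.7
bare surface,S1,97.7,73.4
bare surface,S1+,96.7,83.8
bare surface,S2+S1+,99.4,90.1
bare surface,S2+S1+DEM,100.0,90.1
water,S2,87.0,100.0
water,S2+,81.3,100.0
water,S1,100.0,88.5
water,S1+,97.7,96.6
water,S2+S1+,97.8,100.0
water,S2+S1+DEM,97.8,100.0
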