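source_code,target_class,source_name
0,forest,primf
1,grassland,primn
2,forest,secdf
3,grassland,secdn
4,urban,urban
5,cropland,c3ann
6,cropland,c4ann
7,cropland,c3per
8,cropland,c4per
9,cropland,c3nfx
10,grassland,pastr
11,grassland,range
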