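source_code,target_class,source_name
10,cropland,cropland_rainfed
20,cropland,cropland_irrigated
30,cropland,mosaic_cropland
40,grassland,mosaic_natural_vegetation
50,forest,tree_broadleaved_evergreen
60,forest,tree_broadleaved_deciduous
70,forest,tree_needleleaved_evergreen
80,forest,tree_needleleaved_deciduous
90,forest,tree_mixed
100,forest,mosaic_tree_shrub
110,grassland,mosaic_herbaceous
120,grassland,shrubland
130,grassland,grassland
140,barren,lichens_mosses
150,barren,sparse_vegetation
160,forest,tree_flooded_fresh
170,forest,tree_flooded_saline
180,water,shrub_herbaceous_flooded
190,urban,urban
200,barren,bare_areas
210,water,water_bodies
220,barren,permanent_snow_ice
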