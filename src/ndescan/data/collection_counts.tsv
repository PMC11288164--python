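study	category	body_site	count
hmp_assembled_genomes	mag		2820
ehomd_v10	mag		8622
hrgm_catalog	mag		6185
cultivated_gut_reference	pure_culture		3324
gut_culture_biobank	pure_culture		97
browne_culture_collection	pure_culture		216
human_oral_v1	mag		452
uhgg_catalog	mag		4579
ihmp_assembled	assembled_metagenome		558
chen_gut	read_sample	gut	107
wang_gut	read_sample	gut	162
mas_lloret_gut	read_sample	gut	9
zhang_gut	read_sample	gut	234
zhang_oral	read_sample	oral	295
ren_lung	read_sample	lung	38
zheng_lung	read_sample	lung	47
feigelman_lung	read_sample	lung	18
ma_gut	read_sample	gut	128
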