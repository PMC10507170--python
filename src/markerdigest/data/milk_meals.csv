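species,fresh_milk_g_per_kg_bw,protein_g_per_kg_bw,dm_g_per_kg_bw,tio2_mg_per_g_dm
bovine,55.3,2.0,7.2,5.45
caprine,63.1,2.0,7.1,5.45
ovine,31.9,2.0,5.6,5.45
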