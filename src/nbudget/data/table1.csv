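region_id,landuse,item,kgN_per_yr
national,cropland,N fertilizer,28900000000
national,cropland,N deposition,5900000000
national,cropland,irrigation,700000000
national,cropland,livestock manure,5300000000
national,cropland,human excretion,1600000000
national,cropland,cropland BNF,4600000000
national,cropland,straw recycle,2400000000
national,forest,N fertilizer,2400000000
national,forest,N deposition,5500000000
national,forest,forest BNF,4100000000
national,grassland,N fertilizer,600000000
national,grassland,grassland BNF,3000000000
national,grassland,N deposition,3500000000
national,grassland,irrigation for artificial grassland,0
national,grassland,livestock manure,3700000000
national,water,cropland runoff,2400000000
national,water,livestock runoff,1000000000
national,water,forest runoff,1300000000
national,water,human wastewater discharged,1900000000
national,water,industrial wastewater,2300000000
national,water,WTP effluent,1200000000
national,water,N deposition,600000000
national,built-up,N deposition,1000000000
national,unused,N deposition,1600000000
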