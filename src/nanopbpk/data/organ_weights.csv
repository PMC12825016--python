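species,organ,weight_g,lumped_compartment,provenance
mouse,heart,0.162,others,printed
mouse,liver,1.45,mps,printed
mouse,spleen,0.1166,mps,printed
mouse,lungs,0.515,lungs,printed
mouse,kidneys,0.496,kidneys,printed
mouse,brain,0.474,others,printed
mouse,stomach,0.587,others,printed
mouse,small_intestine,1.28,others,printed
mouse,large_intestine,0.55,others,printed
mouse,tail,0.018,others,printed
mouse,carcass,10.2,others,printed
human,heart,310,others,printed
human,liver,1690,mps,printed
human,spleen,192,mps,printed
human,lungs,1170,lungs,printed
human,kidneys,280,kidneys,printed
human,brain,1450,others,printed
human,gi_tract,1650,others,printed
human,muscle,35000,others,printed
human,parotid,27.5,others,printed
human,thyroid,16.4,others,printed
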