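species,genus,family,order,class,phylum,endpoint,effect,duration_h,concentration,unit,source_ref
Daphnia magna,Daphnia,Daphniidae,Anomopoda,Branchiopoda,Arthropoda,EC50,immobility,48,770,ugL,measured-23
Ceriodaphnia dubia,Ceriodaphnia,Daphniidae,Anomopoda,Branchiopoda,Arthropoda,EC50,immobility,48,958,ugL,measured-24
Thamnocephalus platyurus,Thamnocephalus,Thamnocephalidae,Anostraca,Branchiopoda,Arthropoda,LC50,mortality,96,5200,ugL,measured-25
Tigriopus japonicus,Tigriopus,Harpacticidae,Harpacticoida,Copepoda,Arthropoda,LC50,mortality,96,2150,ugL,measured-26
Hyalella azteca,Hyalella,Hyalellidae,Amphipoda,Malacostraca,Arthropoda,LC50,mortality,96,218000,ugL,measured-27
Oncorhynchus mykiss,Oncorhynchus,Salmonidae,Salmoniformes,Actinopterygii,Chordata,LC50,mortality,96,603000,ugL,measured-28
Pomatoschistus microps,Pomatoschistus,Gobiidae,Gobiiformes,Actinopterygii,Chordata,LC50,mortality,96,305000,ugL,measured-29
Pseudokirchneriella subcapitata,Pseudokirchneriella,Chlorodendraceae,Chlorodendrales,Chlorodendrophyceae,Chlorophyta,EC50,respiratory_inhibition,96,580,ugL,measured-30
Tetraselmis chuii,Tetraselmis,Chlorodendraceae,Chlorodendrales,Chlorodendrophyceae,Chlorophyta,EC50,respiratory_inhibition,96,145,ugL,measured-31
Vibrio fischeri,Vibrio,Vibrionaceae,Vibrionales,Gammaproteobacteria,Proteobacteria,EC50,respiratory_inhibition,96,1000000,ugL,measured-32
Paracentrotus lividus,Paracentrotus,Parechinidae,Camarodonta,Echinoidea,Echinodermata,LC50,mortality,96,2610,ugL,measured-33
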