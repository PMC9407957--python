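surrogate,species,genus,family,order,class,phylum,endpoint,effect,duration_h,concentration,unit,cv_success_pct,mse,r2,taxonomic_distance,source_ref
Daphnia magna,Thamnocephalus platyurus,Thamnocephalus,Thamnocephalidae,Anostraca,Branchiopoda,Arthropoda,LC50,mortality,96,724.26,ugL,91,0.05,0.98,4,webice-dm
Daphnia magna,Daphnia pulex,Daphnia,Daphniidae,Anomopoda,Branchiopoda,Arthropoda,EC50,immobility,48,628.65,ugL,90,0.12,0.97,1,webice-dm
Daphnia magna,Simocephalus serrulatus,Simocephalus,Daphniidae,Anomopoda,Branchiopoda,Arthropoda,EC50,immobility,48,755.41,ugL,87,0.21,0.88,2,webice-dm
Daphnia magna,Utterbackia imbecillis,Utterbackia,Unionidae,Unionida,Bivalvia,Mollusca,LC50,mortality,96,580.28,ugL,100,0.11,0.96,4,webice-dm
Daphnia magna,Amblema plicata,Amblema,Unionidae,Unionida,Bivalvia,Mollusca,LC50,mortality,96,279.27,ugL,90,0.18,0.94,4,webice-dm
Daphnia magna,Megalonaias nervosa,Megalonaias,Unionidae,Unionida,Bivalvia,Mollusca,LC50,mortality,96,437.8,ugL,91,0.16,0.96,3,webice-dm
Daphnia magna,Margaritifera falcata,Margaritifera,Margaritiferidae,Unionida,Bivalvia,Mollusca,LC50,mortality,96,787.86,ugL,90,0.14,0.95,3,webice-dm
Oncorhynchus mykiss,Salmo salar,Salmo,Salmonidae,Salmoniformes,Actinopterygii,Chordata,LC50,mortality,96,61347.21,ugL,93,0.12,0.95,2,webice-om
Oncorhynchus mykiss,Salvelinus fontinalis,Salvelinus,Salmonidae,Salmoniformes,Actinopterygii,Chordata,LC50,mortality,96,60703.33,ugL,92,0.11,0.94,2,webice-om
Oncorhynchus mykiss,Salmo trutta,Salmo,Salmonidae,Salmoniformes,Actinopterygii,Chordata,LC50,mortality,96,61269.36,ugL,96,0.1,0.95,2,webice-om
Oncorhynchus mykiss,Oncorhynchus tshawytscha,Oncorhynchus,Salmonidae,Salmoniformes,Actinopterygii,Chordata,LC50,mortality,96,60424.03,ugL,94,0.07,0.96,1,webice-om
Oncorhynchus mykiss,Oncorhynchus kisutch,Oncorhynchus,Salmonidae,Salmoniformes,Actinopterygii,Chordata,LC50,mortality,96,79193.94,ugL,100,0.04,0.98,1,webice-om
Oncorhynchus mykiss,Oncorhynchus clarkii,Oncorhynchus,Salmonidae,Salmoniformes,Actinopterygii,Chordata,LC50,mortality,96,44376.05,ugL,95,0.09,0.94,1,webice-om
Oncorhynchus mykiss,Lepomis cyanellus,Lepomis,Centrarchidae,Perciformes,Actinopterygii,Chordata,LC50,mortality,96,85160.74,ugL,100,0.13,0.94,4,webice-om
Oncorhynchus mykiss,Salvelinus namaycush,Salvelinus,Salmonidae,Salmoniformes,Actinopterygii,Chordata,LC50,mortality,96,28786.62,ugL,96,0.08,0.93,2,webice-om
Oncorhynchus mykiss,Perca flavescens,Perca,Percidae,Perciformes,Actinopterygii,Chordata,LC50,mortality,96,50142.3,ugL,88,0.14,0.94,4,webice-om
Hyalella azteca,Gammarus pseudolimnaeus,Gammarus,Gammaridae,Amphipoda,Malacostraca,Arthropoda,LC50,mortality,96,2161.17,ugL,100,0.03,0.99,3,webice-ha
Hyalella azteca,Pimephales promelas,Pimephales,Cyprinidae,Cypriniformes,Actinopterygii,Chordata,LC50,mortality,96,3457.14,ugL,97,0.22,0.85,4,webice-ha
Hyalella azteca,Americamysis bahia,Americamysis,Mysidae,Mysida,Malacostraca,Arthropoda,LC50,mortality,96,350.71,ugL,86,0.20,0.86,4,webice-ha
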