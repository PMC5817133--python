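species,genus,mass_kg,delta_tbc,delta_tair,source,mass_estimated
Aldabrachelys gigantea,Aldabrachelys,165.2,5.0,5.0,synthetic-study-1,True
Chelonoidis nigra,Chelonoidis,138.9,3.6,5.0,synthetic-study-2,True
Stigmochelys pardalis,Stigmochelys,27.2,6.7,7.2,synthetic-study-3,True
Testudo graeca,Testudo,1.1,11.9,11.7,synthetic-study-4,True
Testudo hermanni,Testudo,1.2,12.0,12.1,synthetic-study-5,True
Testudo marginata,Testudo,1.4,9.5,10.5,synthetic-study-6,True
Aldabrachelys gigantea,Aldabrachelys,182.3,5.7,6.5,synthetic-study-1,True
Chelonoidis nigra,Chelonoidis,91.9,8.6,9.5,synthetic-study-2,False
Stigmochelys pardalis,Stigmochelys,28.0,7.0,7.1,synthetic-study-3,False
Testudo graeca,Testudo,0.6,11.2,11.2,synthetic-study-4,False
Testudo hermanni,Testudo,1.4,8.3,9.0,synthetic-study-5,False
Testudo marginata,Testudo,1.7,11.3,10.9,synthetic-study-6,False
Aldabrachelys gigantea,Aldabrachelys,50.8,4.8,5.8,synthetic-study-1,False
Chelonoidis nigra,Chelonoidis,134.4,7.9,8.3,synthetic-study-2,False
Stigmochelys pardalis,Stigmochelys,30.5,7.7,8.2,synthetic-study-3,False
Testudo graeca,Testudo,0.9,11.6,11.8,synthetic-study-4,False
Testudo hermanni,Testudo,0.7,10.3,10.4,synthetic-study-5,False
Testudo marginata,Testudo,2.5,6.0,6.5,synthetic-study-6,False
Aldabrachelys gigantea,Aldabrachelys,92.7,5.1,5.8,synthetic-study-1,False
Chelonoidis nigra,Chelonoidis,68.9,5.7,5.5,synthetic-study-2,False
Stigmochelys pardalis,Stigmochelys,19.9,7.0,7.4,synthetic-study-3,False
Testudo graeca,Testudo,1.3,11.5,11.3,synthetic-study-4,False
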