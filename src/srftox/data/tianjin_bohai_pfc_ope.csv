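name,abbr,family,cas,formula,half_life_days,medium,mec_ng_per_l,pnec_ng_per_l,c_reference
Perfluorooctane sulphonate,PFOS,perfluorinated compound,1763-23-1,C8HF17O3S,1.48E4,water,1.61,1000,0.0041
Perfluorooctanoic acid,PFOA,perfluorinated compound,335-67-1,C8HO2F15,1.58E3,water,15.1,1.0E5,0.038
Triethyl phosphate,TEP,organophosphate ester,78-40-0,C6H15O4P,4.90,water,1.683,9.0E5,12.24
Tri(2-ethylhexyl) phosphate,TEHP,organophosphate ester,78-42-2,C24H51O4P,4.23,water,47.4,5.0E5,14.18
Tri(2-chloroethyl) phosphate,TCEP,organophosphate ester,115-96-8,C6H12Cl3O4P,3.68,water,473.79,5.1E4,16.30
Tris(1-chloro-2-propyl) phosphate,TCPP,organophosphate ester,13674-84-5,C9H18Cl3O4P,3.68,water,6.3,4.5E4,16.30
"Tris(1,3-dichloro-2-propyl) phosphate",TDCP,organophosphate ester,13674-87-8,C12H15Cl6O4P,4.08,water,3.249,3.9E4,14.71
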