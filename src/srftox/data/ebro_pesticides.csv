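name,cas,formula,half_life_days,medium,mec_ng_per_l,pnec_ng_per_l,c_reference
Carbendazim,10605-21-7,C9H9N3O2,8,water,2.78,1.5,7.5
Fenitrothion,122-14-5,C9H12NO5PS,86.1,water,0.11,0.09,0.70
Hexythiazox,78587-05-0,C17H21ClN2O2S,24.6,water,7.41,6.1,2.44
Imazalil,35554-44-0,C14H14Cl2N2O,151,water,61.01,92,0.40
Metolachlor,51218-45-2,C15H22ClNO2,39,water,0.55,1,1.54
Prochloraz,67747-09-5,C15H16Cl3N3O2,60,water,15.59,18,1
Propazine,139-40-2,C9H16ClN5,90,water,0.14,40,0.67
Tebuconazole,107534-96-3,C16H22ClN3O,62,water,2.36,100,0.97
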