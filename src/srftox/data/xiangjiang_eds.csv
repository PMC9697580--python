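name,cas,formula,half_life_days,medium,mec_ng_per_l,pnec_ng_per_l,c_reference
Progesterone,57-83-0,C21H30O2,666.66,water,8.1,415,0.09
Testosterone,58-22-0,C19H28O2,1.17 × 10^4,water,6.5,100,5.1 × 10^-3
Androstenedione,1963-5-8,C19H26O2,1.12 × 10^3,water,4.4,14,5.4 × 10^-2
Estrone,53-16-7,C18H22O2,1.06 × 10^5,water,51.33,6,5.7 × 10^-4
Bisphenol A,1980-5-7,C15H16O2,4.02 × 10^6,water,30.9,2000,1.5 × 10^-5
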