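variable,level,insulin_degludec,insulin_detemir,insulin_glargine
sex,Female,101,162,3481
sex,Male,53,82,1649
sex,NA,3,5,250
country,United States,146,236,5173
country,Japan,0,0,2
country,United Kingdom,2,1,4
country,China,1,0,8
country,Others,7,0,193
age_group,<18,0,0,1
age_group,18-64,28,54,1286
age_group,>65,41,70,2255
age_group,NA,87,125,1863
year,2008,0,0,3
year,2009,0,2,66
year,2010,0,0,72
year,2011,0,1,62
year,2012,0,3,71
year,2013,0,2,197
year,2014,0,0,325
year,2015,0,13,349
year,2016,5,26,330
year,2017,10,31,370
year,2018,7,22,440
year,2019,13,32,373
year,2020,24,22,547
year,2021,26,21,750
year,2022,16,20,496
year,2023,11,19,363
year,2024,34,31,351
year,2025,10,4,215
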