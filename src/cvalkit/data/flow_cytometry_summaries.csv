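species,sex,one_c_pg,genome_mb,se_mb,n,standard
Calliptamus barbarus,F,10.31,10083,36,5,Locusta migratoria
Calliptamus barbarus,M,9.90,9679,52,3,Locusta migratoria
Calliptamus abbreviatus,F,10.03,9813,84,5,Locusta migratoria
Calliptamus abbreviatus,M,9.64,9424,11,4,Locusta migratoria
Shirakiacris shirakii,F,7.06,6906,75,2,Locusta migratoria
Shirakiacris shirakii,M,6.57,6429,30,4,Periplaneta americana
Pedopodisma tsinlingensis,F,11.09,10847,91,3,Locusta migratoria
Pedopodisma tsinlingensis,M,10.21,9990,,1,Periplaneta americana
Sinopodisma qinlingensis,F,11.35,11102,14,5,Locusta migratoria
Sinopodisma qinlingensis,M,10.96,10719,20,4,Locusta migratoria
Fruhstorferiola huayinensis,F,8.62,8433,10,5,Locusta migratoria
Fruhstorferiola huayinensis,M,8.30,8120,26,4,Locusta migratoria
Bryodemella holdereri,F,18.64,18232,143,3,Locusta migratoria
Bryodemella holdereri,M,18.19,17787,23,3,Locusta migratoria
Oedaleus asiaticus,F,9.83,9616,59,4,Periplaneta americana
Oedaleus asiaticus,M,9.24,9041,16,4,Locusta migratoria
Oedaleus infernalis,F,9.83,9612,89,3,Locusta migratoria
Oedaleus infernalis,M,9.27,9070,50,4,Locusta migratoria
Epacromius coerulipes,F,8.55,8362,63,3,Locusta migratoria
Epacromius coerulipes,M,8.14,7958,20,3,Locusta migratoria
Trilophidia annulata,F,10.06,9840,26,3,Locusta migratoria
Trilophidia annulata,M,9.37,9159,46,3,Locusta migratoria
Pararcyptera microptera meridionalis,F,13.88,13579,18,3,Locusta migratoria
Pararcyptera microptera meridionalis,M,13.13,12837,37,4,Locusta migratoria
Euchorthippus unicolor,F,11.20,10956,155,3,Locusta migratoria
Euchorthippus unicolor,M,10.33,10107,143,3,Locusta migratoria
Acrida cinerea,F,11.24,10995,48,3,Locusta migratoria
Acrida cinerea,M,10.64,10404,37,3,Locusta migratoria
Haplotropis brunneriana,F,14.45,14130,19,4,Locusta migratoria
Haplotropis brunneriana,M,13.65,13347,10,4,Locusta migratoria
Filchnerella rubimargina,F,14.21,13898,36,4,Locusta migratoria
Filchnerella rubimargina,M,13.51,13211,73,5,Locusta migratoria
Atractomorpha sinensis,F,8.21,8026,104,3,Locusta migratoria
Atractomorpha sinensis,M,7.55,7381,25,3,Locusta migratoria
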