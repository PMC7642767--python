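species,female_pg,n_female,male_pg,n_male,p
Calliptamus barbarus,10.31,5,9.90,3,0.001
Calliptamus abbreviatus,10.03,5,9.64,4,0.009
Shirakiacris shirakii,7.06,2,6.57,4,0.002
Pedopodisma tsinlingensis,11.09,3,10.21,1,0.042
Sinopodisma qinlingensis,11.35,5,10.96,4,0.000
Fruhstorferiola huayinensis,8.62,5,8.30,4,0.000
Bryodemella holdereri,18.64,3,18.19,3,0.030
Oedaleus asiaticus,9.83,4,9.24,4,0.001
Oedaleus infernalis,9.83,3,9.27,4,0.002
Epacromius coerulipes,8.55,3,8.14,3,0.004
Trilophidia annulata,10.06,3,9.37,3,0.000
Pararcyptera microptera meridionalis,13.88,3,13.13,4,0.000
Euchorthippus unicolor,11.20,3,10.33,3,0.016
Acrida cinerea,11.24,3,10.64,3,0.001
Haplotropis brunneriana,14.45,4,13.65,4,0.000
Filchnerella rubimargina,14.21,4,13.51,5,0.000
Atractomorpha sinensis,8.21,3,7.55,3,0.004
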