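species,n,sd,fcm_pg,kmer_pg,p
Calliptamus abbreviatus,4,0.02,9.64,9.36,0.00
Haplotropis brunneriana,4,0.04,14.45,14.19,0.01
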