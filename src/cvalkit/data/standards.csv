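name,sex,one_c_pg
Periplaneta americana,M,3.41
Locusta migratoria,M,6.20
Gallus domesticus,M,1.165
Mus musculus,M,3.30
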