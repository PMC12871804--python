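(((((((((Homo_sapiens:0.5,Homo_neanderthalensis:0.45):6.0,(Pan_troglodytes:2.5,Pan_paniscus:2.5):4.0):2.5,Gorilla_gorilla:9.0):7.0,Pongo_abelii:16.0):4.0,(Symphalangus_syndactylus:7.0,Hoolock_hoolock:7.0):13.0):9.0,(Macaca_mulatta:18.0,Colobus_guereza:18.0):11.0):14.0,Callithrix_jacchus:43.0):26.0,Carlito_syrichta:69.0):5.0,Lemur_catta:74.0);
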