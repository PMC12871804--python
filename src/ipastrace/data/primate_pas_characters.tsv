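tip	presence	count
Homo_sapiens	present	3
Homo_neanderthalensis	present	3
Pan_troglodytes	present	1
Pan_paniscus	present	1
Gorilla_gorilla	present	1
Pongo_abelii	present	1
Symphalangus_syndactylus	present	2
Hoolock_hoolock	present	2
Macaca_mulatta	present	1
Colobus_guereza	present	0
Callithrix_jacchus	lost	NA
Carlito_syrichta	absent	NA
Lemur_catta	absent	NA
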