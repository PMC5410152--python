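species	higher_taxon	limbless
Sphenodon_punctatus	Rhynchocephalia	0
Amalosia_lesueurii	Gekkota	0
Strophurus_williamsi	Gekkota	0
Eublepharis_macularius	Gekkota	0
Tarentola_annularis	Gekkota	0
Chondrodactylus_turneri	Gekkota	0
Gehyra_variegata	Gekkota	0
Mabuya_sp	Scincoidea	0
Calyptommatus_sinebrachiatus	Lacertiformes	0
Nothobachia_ablephara	Lacertiformes	0
Zootoca_vivipara	Lacertiformes	0
Python_sebae	Serpentes	1
Thamnophis_sirtalis	Serpentes	1
Boaedon_fuliginosus	Serpentes	1
Vipera_aspis	Serpentes	1
Varanus_rosenbergi	Anguimorpha	0
Varanus_indicus	Anguimorpha	0
Varanus_panoptes	Anguimorpha	0
Iguana_iguana	Iguania	0
Uta_stansburiana	Iguania	0
Anolis_sagrei	Iguania	0
Liolaemus_gravenhorsti	Iguania	0
Liolaemus_tenuis	Iguania	0
Tropidurus_torquatus	Iguania	0
Chamaeleo_calyptratus	Iguania	0
Furcifer_lateralis	Iguania	0
Pogona_vitticeps	Iguania	0
Calotes_versicolor	Iguania	0
Agama_impalearis	Iguania	0
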