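# Fossil calibration ages (Ma), total-group (stem) semantics: each row dates
# the parent of the MRCA of `tips` (the split of the named lineage from its
# sister).  Derived ages that are pure +3-step propagations of other rows
# (Iguania 105 = 99+3+3, Acrodonta 102 = 99+3) are not encoded as independent
# calibrations; the propagation rule regenerates them.
clade,tips,age_ma,stem,note
Sauria,Sphenodon_punctatus;Iguana_iguana,256,1,root of the lepidosaur sample
Rhynchocephalia,Sphenodon_punctatus,238,1,resolves to the root; superseded by the older Sauria age
Chamaeleonidae,Chamaeleo_calyptratus;Furcifer_lateralis,99,1,
Agamidae,Pogona_vitticeps;Calotes_versicolor;Agama_impalearis,99,1,
Chamaeleo,Chamaeleo_calyptratus,13,1,
Tropiduridae,Tropidurus_torquatus,15,1,
Iguanidae,Iguana_iguana,56,1,
Anolis,Anolis_sagrei,20,1,
Gekkota,Amalosia_lesueurii;Gehyra_variegata,150,1,
Gekkonidae,Chondrodactylus_turneri;Gehyra_variegata,15,1,
Diplodactylidae,Amalosia_lesueurii;Strophurus_williamsi,20,1,
Serpentes,Python_sebae;Vipera_aspis,167,1,
Pythonidae,Python_sebae,35,1,
Colubridae,Thamnophis_sirtalis,31,1,
Lamprophiidae,Boaedon_fuliginosus,17,1,based on an elapoid fossil
Viperidae,Vipera_aspis,20,1,
Anguimorpha,Varanus_indicus;Varanus_panoptes,145,1,
Lacertiformes,Zootoca_vivipara;Nothobachia_ablephara,99,1,
Gymnophthalmidae,Calyptommatus_sinebrachiatus;Nothobachia_ablephara,66,1,dated by the oldest teiid (sister group)
Scincoidea,Mabuya_sp,150,1,
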