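(Sphenodon_punctatus,(((Amalosia_lesueurii,Strophurus_williamsi),(Eublepharis_macularius,(Tarentola_annularis,(Chondrodactylus_turneri,Gehyra_variegata)))),(Mabuya_sp,((Zootoca_vivipara,(Calyptommatus_sinebrachiatus,Nothobachia_ablephara)),((Python_sebae,(Boaedon_fuliginosus,(Thamnophis_sirtalis,Vipera_aspis))),((Varanus_indicus,(Varanus_rosenbergi,Varanus_panoptes)),(((Chamaeleo_calyptratus,Furcifer_lateralis),(Pogona_vitticeps,(Calotes_versicolor,Agama_impalearis))),(Tropidurus_torquatus,(Iguana_iguana,((Uta_stansburiana,Anolis_sagrei),(Liolaemus_gravenhorsti,Liolaemus_tenuis)))))))))));
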