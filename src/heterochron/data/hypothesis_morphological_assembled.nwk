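(Sphenodon_punctatus,((((Chamaeleo_calyptratus,Furcifer_lateralis),(Calotes_versicolor,(Agama_impalearis,Pogona_vitticeps))),(Tropidurus_torquatus,(Iguana_iguana,((Uta_stansburiana,Anolis_sagrei),(Liolaemus_gravenhorsti,Liolaemus_tenuis))))),(((Amalosia_lesueurii,Strophurus_williamsi),(Eublepharis_macularius,(Tarentola_annularis,(Chondrodactylus_turneri,Gehyra_variegata)))),((Mabuya_sp,(Zootoca_vivipara,(Calyptommatus_sinebrachiatus,Nothobachia_ablephara))),((Varanus_indicus,(Varanus_rosenbergi,Varanus_panoptes)),(Python_sebae,(Boaedon_fuliginosus,(Thamnophis_sirtalis,Vipera_aspis))))))));
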