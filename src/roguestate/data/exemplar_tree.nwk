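(Amborella_trichopoda,(((Cabomba_caroliniana,Brasenia_schreberi)Cabombaceae,(Nuphar_lutea,(Nymphaea_alba,Victoria_amazonica)Nymphaeoideae)Nymphaeaceae)Nymphaeales,((Austrobaileya_scandens,(Illicium_anisatum,Schisandra_chinensis))Austrobaileyales,((((Sarcandra_glabra,Chloranthus_spicatus),(Hedyosmum_orientale,Ascarina_rubricaulis))Chloranthaceae,((Magnolia_grandiflora,Liriodendron_tulipifera),((Laurus_nobilis,Piper_nigrum),(Drimys_winteri,Canella_winterana)))Magnoliids),((Acorus_calamus,(((Arum_maculatum,Spathiphyllum_wallisii)Araceae,((Tofieldia_calyculata,Pleea_tenuifolia)Tofieldiaceae,(Alisma_plantago,Potamogeton_natans)))Alismatales,(Lilium_martagon,(Dioscorea_communis,Oryza_sativa))))Monocots,(Ceratophyllum_demersum,(((Euptelea_pleiosperma,(Papaver_somniferum,Eschscholzia_californica)Papaveraceae),(Ranunculus_acris,Aquilegia_vulgaris))Ranunculales,((Trochodendron_aralioides,Buxus_sempervirens),((Arabidopsis_thaliana,Citrus_aurantium),(Asclepias_syriaca,Helianthus_annuus))))Eudicots)))Mesangiosperms)))Angiosperms;
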