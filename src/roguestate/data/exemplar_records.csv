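taxon,fusion_any,fusion_type,clade,note
Amborella_trichopoda,no,none,Amborellales,carpels free
Cabomba_caroliniana,no,none,Cabombaceae,carpels free
Brasenia_schreberi,no,none,Cabombaceae,carpels free
Nuphar_lutea,yes,congenital,Nymphaeaceae,syncarpous
Nymphaea_alba,yes,congenital,Nymphaeoideae,syncarpous
Victoria_amazonica,yes,congenital,Nymphaeoideae,syncarpous
Austrobaileya_scandens,no,none,Austrobaileyales,carpels free
Illicium_anisatum,no,none,Austrobaileyales,carpels free
Schisandra_chinensis,no,none,Austrobaileyales,carpels free
Sarcandra_glabra,inapplicable,unknown,Chloranthaceae,monomerous; editable placeholder
Chloranthus_spicatus,inapplicable,unknown,Chloranthaceae,monomerous; editable placeholder
Hedyosmum_orientale,inapplicable,unknown,Chloranthaceae,monomerous; editable placeholder
Ascarina_rubricaulis,inapplicable,unknown,Chloranthaceae,monomerous; editable placeholder
Magnolia_grandiflora,no,none,Magnoliids,carpels free
Liriodendron_tulipifera,no,none,Magnoliids,carpels free
Laurus_nobilis,inapplicable,unknown,Magnoliids,monomerous; editable placeholder
Piper_nigrum,yes,congenital,Magnoliids,syncarpous; editable placeholder
Drimys_winteri,no,none,Magnoliids,carpels free
Canella_winterana,yes,congenital,Magnoliids,syncarpous
Acorus_calamus,yes,congenital,Monocots,syncarpous
Arum_maculatum,yes,congenital,Araceae,syncarpous
Spathiphyllum_wallisii,yes,congenital,Araceae,syncarpous
Tofieldia_calyculata,no,none,Tofieldiaceae,carpels nearly free; editable placeholder
Pleea_tenuifolia,no,none,Tofieldiaceae,carpels nearly free; editable placeholder
Alisma_plantago,no,none,Alismatales,carpels free
Potamogeton_natans,no,none,Alismatales,carpels free
Lilium_martagon,yes,congenital,Monocots,syncarpous
Dioscorea_communis,yes,congenital,Monocots,syncarpous
Oryza_sativa,yes,congenital,Monocots,syncarpous; editable placeholder
Euptelea_pleiosperma,no,none,Eupteleaceae,carpels free
Papaver_somniferum,yes,congenital,Papaveraceae,syncarpous
Eschscholzia_californica,yes,congenital,Papaveraceae,syncarpous
Ranunculus_acris,no,none,Ranunculales,carpels free
Aquilegia_vulgaris,no,none,Ranunculales,carpels free
Trochodendron_aralioides,yes,congenital,Eudicots,basally united; editable placeholder
Buxus_sempervirens,yes,congenital,Eudicots,syncarpous
Arabidopsis_thaliana,yes,congenital,Eudicots,syncarpous
Citrus_aurantium,yes,both,Eudicots,congenital ovary with postgenital stylar union
Asclepias_syriaca,yes,postgenital,Eudicots,carpels postgenitally united by stigma
Helianthus_annuus,yes,congenital,Eudicots,syncarpous
Ceratophyllum_demersum,unknown,unknown,Ceratophyllales,monomerous vs pseudomonomerous disputed
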