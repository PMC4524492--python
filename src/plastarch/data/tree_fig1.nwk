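(((Marsupiomonas_sp_NIES1824,(Pedinomonas_minor,Pedinomonas_tuberculata))Pedinophyceae,(Dicloster_acuatus,Parachlorella_kessleri,(Pseudochloris_wilhelmii,Marvania_geminata),(Chlorella_vulgaris,Chlorella_variabilis))Chlorellales)Pedino_Chlorellales,(((Oocystis_solitaria,Planctonema_lauterbornii)Oocystis_clade,(Koliella_corcontica,(Gloeotilopsis_sterilis,(Geminella_terricola,Geminella_minor)))Geminella_clade)Geminella_Oocystis,((Pleurastrosarcina_brevispinosa,(Neocystis_brevis,(Chlorella_mirabilis,(Pabia_signiensis,Koliella_longiseta),(Stichococcus_bacillaris,Prasiolopsis_sp_SAG8481)))Prasiola_clade)Prasiolales,((Parietochloris_pseudoalveolaris,((Xylochloris_irregularis,Leptosira_terrestris)Xylochloris_Leptosira,(Microthamnion_kuetzingianum,Fusochloris_perforata)Microthamniales)Xylochloris_Microthamniales)Parietochloris_Xylochloris,(Trebouxia_aggregata,(Myrmecia_israelensis,Lobosphaera_incisa)Lobosphaera_clade,(Dictyochloropsis_reticulata,Watanabea_reniformis)Watanabea_clade,((Choricystis_minor,Botryococcus_braunii)Choricystis_clade,(Elliptochloris_bilobata,Trebouxiophyceae_sp_MX_AZ01,Coccomyxa_subellipsoidea,Paradoxia_multiseta)Elliptochloris_clade)Elliptochloris_Choricystis)IR_loss_superclade)Late_core))Core_Trebouxiophyceae)Root;
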