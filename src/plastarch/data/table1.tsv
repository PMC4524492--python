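taxon	display_name	accession	clade	at_percent	genome_bp	ir_bp	lsc_bp	ssc_bp	genes	introns_gI	introns_gII	repeat_percent	ir_structure	ir_rdna	complete
Marsupiomonas_sp_NIES1824	Marsupiomonas sp. NIES 1824	KM462870	Pedinophyceae	59.7	94262	9926	68185	6225	106	0	0	0.3	1	1	1
Pedinomonas_tuberculata	Pedinomonas tuberculata	KM462867	Pedinophyceae	66.6	126694	16074	86619	7927	107	5	5	2.1	1	1	1
Pedinomonas_minor	Pedinomonas minor	NC_016733	Pedinophyceae	65.2	98340	10639	70398	6664	106	0	0	0.0	1	1	1
Dicloster_acuatus	Dicloster acuatus	KM462885	Chlorellales	70.0	169201	22061	87535	37544	112	6	0	5.4	1	1	1
Parachlorella_kessleri	Parachlorella kessleri	NC_012978	Chlorellales	70.0	123994	10913	88297	13871	112	1	0	4.0	1	1	1
Pseudochloris_wilhelmii	Pseudochloris wilhelmii	KM462886	Chlorellales	63.3	109775	12798	66211	17968	113	1	0	4.2	1	1	1
Marvania_geminata	Marvania geminata	KM462888	Chlorellales	61.8	108470				113	1	0	3.0	0	0	1
Chlorella_vulgaris	Chlorella vulgaris	NC_001865	Chlorellales	68.4	150613				113	3	0	7.3	0	0	1
Chlorella_variabilis	Chlorella variabilis	NC_015359	Chlorellales	65.9	124579				113	3	0	2.4	0	0	1
Koliella_corcontica	"Koliella" corcontica	KM462874	Geminella_clade	72.0	117543	15891	77346	8415	105	8	0	11.6	1	1	1
Geminella_terricola	Geminella terricola	KM462881	Geminella_clade	67.3	187843	18786	139317	10954	109	1	1	22.7	1	1	1
Geminella_minor	Geminella minor	KM462883	Geminella_clade	72.1	129187	11970	95317	9930	108	1	1	3.2	1	1	1
Gloeotilopsis_sterilis	Gloeotilopsis sterilis	KM462877	Geminella_clade	70.5	132626	13730	95069	10097	109	2	0	15.1	1	1	1
Oocystis_solitaria	Oocystis solitaria	FJ968739	Oocystis_clade	71.0	96287		71295		110	1	0	10.7	1	1	0
Planctonema_lauterbornii	Planctonema lauterbornii	KM462880	Oocystis_clade	66.8	114128	10577	81906	11068	111	1	0	7.3	1	1	1
Pleurastrosarcina_brevispinosa	Pleurastrosarcina brevispinosa	KM462875	Prasiolales	65.5	295314	45468	194027	10351	111	16	3	21.3	1	1	0
Neocystis_brevis	Neocystis brevis	KM462873	Prasiola_clade	68.6	211747				112	5	0	19.8	0	0	1
Stichococcus_bacillaris	Stichococcus bacillaris	KM462864	Prasiola_clade	68.1	116952	8272	51357	49051	107	4	1	4.3	1	0	1
Prasiolopsis_sp_SAG8481	Prasiolopsis sp. SAG 84.81	KM462862	Prasiola_clade	64.9	306152				108	7	1	23.1	0	0	1
Chlorella_mirabilis	"Chlorella" mirabilis	KM462865	Prasiola_clade	68.5	167972	6835	121087	33215	110	0	0	5.5	1	1	1
Koliella_longiseta	Koliella longiseta	KM462868	Prasiola_clade	68.6	197094	10619	141677	34179	111	0	0	4.0	1	1	1
Pabia_signiensis	Pabia signiensis	KM462866	Prasiola_clade	66.6	236463	27336	141652	40139	111	0	0	20.0	1	1	1
Parietochloris_pseudoalveolaris	Parietochloris pseudoalveolaris	KM462869	Parietochloris	68.4	145947	6786	115976	16399	109	0	0	6.8	1	1	1
Leptosira_terrestris	Leptosira terrestris	NC_009681	Leptosira	72.7	195081				107	4	0	4.8	0	0	1
Xylochloris_irregularis	Xylochloris irregularis	KM462872	Xylochloris	60.3	181542	28473	76371	48225	110	1	5	7.1	1	1	1
Microthamnion_kuetzingianum	Microthamnion kuetzingianum	KM462876	Microthamniales	65.3	158609				107	0	0	16.7	0	0	1
Fusochloris_perforata	Fusochloris perforata	KM462882	Microthamniales	64.9	148459				107	0	0	3.5	0	0	1
Trebouxia_aggregata	Trebouxia aggregata	EU123962-EU124002	Trebouxiales	65.2	245724				100	8	0	42.7	0	0	0
Myrmecia_israelensis	Myrmecia israelensis	KM462861	Lobosphaera_clade	69.6	146596				112	0	0	3.6	0	0	1
Lobosphaera_incisa	Lobosphaera incisa	KM462871	Lobosphaera_clade	72.2	156031				111	1	0	1.4	0	0	1
Dictyochloropsis_reticulata	Dictyochloropsis reticulata	KM462860	Watanabea_clade	64.1	289394				111	3	5	19.7	0	0	1
Watanabea_reniformis	Watanabea reniformis	KM462863	Watanabea_clade	58.8	201425				110	6	1	23.0	0	0	1
Choricystis_minor	Choricystis minor	KM462878	Choricystis_clade	54.6	94206				111	0	0	0.0	0	0	1
Botryococcus_braunii	Botryococcus braunii	KM462884	Choricystis_clade	57.6	172826				112	1	2	9.8	0	0	1
Elliptochloris_bilobata	Elliptochloris bilobata	KM462887	Elliptochloris_clade	54.2	134677				110	3	0	15.1	0	0	1
Trebouxiophyceae_sp_MX_AZ01	Trebouxiophyceae sp. MX-AZ01	NC_018569	Elliptochloris_clade	42.3	149707				114	4	0	0.9	0	0	1
Coccomyxa_subellipsoidea	Coccomyxa subellipsoidea	NC_015084	Elliptochloris_clade	49.2	175731				114	1	0	10.6	0	0	1
Paradoxia_multiseta	Paradoxia multiseta	KM462879	Elliptochloris_clade	49.4	183394				114	1	4	18.6	0	0	1
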