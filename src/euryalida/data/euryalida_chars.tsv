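taxon_name	rank	family	species_count	branched	pattern	pedicellariae	placed	n_arms_min	n_arms_max	max_forks	forks_is_lower_bound	segments_to_first_fork	genera_count	exceptional
Ophiurida	clade	Ophiurida	404	false	none	false	true	NA	NA	NA	false	NA	46	false
Asteronychidae	clade	Asteronychidae	12	false	none	false	true	NA	NA	NA	false	NA	4	false
Astrocharis	genus	Euryalidae	2	false	none	false	true	NA	NA	NA	false	NA	1	false
Astrobrachion	genus	Euryalidae	2	false	none	false	true	NA	NA	NA	false	NA	1	false
Euryale	genus	Euryalidae	2	true	basal	false	true	NA	NA	NA	false	NA	1	false
Trichaster	genus	Euryalidae	3	true	distal	false	true	NA	NA	NA	false	NA	1	false
Asteromorpha	genus	Euryalidae	4	false	none	false	true	NA	NA	NA	false	NA	1	false
Astroceras_kermadecensis	clade	Euryalidae	1	false	none	false	true	NA	NA	NA	false	NA	0	false
Sthenocephalus	genus	Euryalidae	2	true	distal	false	true	NA	NA	NA	false	NA	1	false
Asterostegus	genus	Euryalidae	3	false	none	false	true	NA	NA	NA	false	NA	1	false
Astroceras_nodosum_group	clade	Euryalidae	2	false	none	false	true	NA	NA	NA	false	NA	0	false
Astroceras	genus	Euryalidae	11	false	none	false	true	NA	NA	NA	false	NA	1	false
Asteroschema_clade	clade	Euryalidae	52	false	none	false	true	NA	NA	NA	false	NA	3	false
Astrothamnus	genus	Gorgonocephalidae	2	false	none	true	true	NA	NA	NA	false	NA	1	false
Astrothrombus	genus	Gorgonocephalidae	4	false	none	true	true	NA	NA	NA	false	NA	1	false
Astroclon	genus	Gorgonocephalidae	2	true	distal	true	true	NA	NA	NA	false	NA	1	false
Astrocrius	clade	Gorgonocephalidae	8	false	none	true	true	NA	NA	NA	false	NA	3	false
Astroniwa	genus	Gorgonocephalidae	1	false	none	true	true	NA	NA	NA	false	NA	1	false
Astrochele	genus	Gorgonocephalidae	3	false	none	true	true	NA	NA	NA	false	NA	1	false
Astrochlamys	genus	Gorgonocephalidae	3	false	none	true	true	NA	NA	NA	false	NA	1	false
Astrodendrum	genus	Gorgonocephalidae	6	true	basal	true	true	NA	NA	NA	false	NA	1	false
Gorgonocephalus	genus	Gorgonocephalidae	10	true	basal	true	true	NA	NA	NA	false	NA	1	false
Astrothorax	genus	Gorgonocephalidae	5	false	none	true	true	NA	NA	NA	false	NA	1	false
Asteroporpa	genus	Gorgonocephalidae	11	false	none	true	true	NA	NA	NA	false	NA	1	false
Astrogomphus	genus	Gorgonocephalidae	2	false	none	true	true	NA	NA	NA	false	NA	1	false
Astrophyton	genus	Gorgonocephalidae	1	true	basal	true	true	NA	NA	NA	false	NA	1	false
Astracme	genus	Gorgonocephalidae	1	true	basal	true	true	NA	NA	NA	false	NA	1	false
Astroboa	genus	Gorgonocephalidae	9	true	basal	true	true	NA	NA	NA	false	NA	1	false
Astrochalcis	genus	Gorgonocephalidae	2	true	basal	true	true	NA	NA	NA	false	NA	1	false
Astrocladus	genus	Gorgonocephalidae	11	true	basal	true	true	NA	NA	NA	false	NA	1	false
Astroglymma	genus	Gorgonocephalidae	2	true	basal	true	true	NA	NA	NA	false	NA	1	false
Astrosierra	genus	Gorgonocephalidae	3	true	distal	true	true	NA	NA	NA	false	NA	1	false
Conocladus	genus	Gorgonocephalidae	1	true	basal	true	true	NA	NA	NA	false	NA	1	false
Ophiocrene	genus	Gorgonocephalidae	1	true	basal	true	true	NA	NA	NA	false	NA	1	false
Astrocaneum_herrerai	species	Gorgonocephalidae	1	true	basal	true	false	NA	NA	NA	false	NA	NA	false
Astrocaneum_spinosum	species	Gorgonocephalidae	1	true	basal	true	false	NA	NA	NA	false	NA	NA	false
Astrocnida_isidis	species	Gorgonocephalidae	1	true	distal	true	false	NA	NA	NA	false	NA	NA	false
Astrocyclus_caecilia	species	Gorgonocephalidae	1	true	basal	true	false	NA	NA	NA	false	NA	NA	false
Astrocyclus_somaliensis	species	Gorgonocephalidae	1	true	basal	true	false	NA	NA	NA	false	NA	NA	false
Astrodictyum_panamense	species	Gorgonocephalidae	1	true	basal	true	false	NA	NA	NA	false	NA	NA	false
Astrogordius_cacaoticus	species	Gorgonocephalidae	1	true	basal	true	false	NA	NA	NA	false	NA	NA	false
Astroplegma_expansum	species	Gorgonocephalidae	1	true	basal	true	false	NA	NA	NA	false	NA	NA	false
Astrospartus_mediterraneus	species	Gorgonocephalidae	1	true	basal	true	false	NA	NA	NA	false	NA	NA	false
Astrozona_munita	species	Gorgonocephalidae	1	false	none	true	false	NA	NA	NA	false	NA	NA	false
Ophiozeta_turgida	species	Gorgonocephalidae	1	false	none	true	false	NA	NA	NA	false	NA	NA	false
Schizostella_bifurcata	species	Gorgonocephalidae	1	true	distal	true	false	NA	NA	NA	false	NA	NA	false
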