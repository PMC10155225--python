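taxon_name	rank	family	species_count	branched	pattern	pedicellariae	placed	n_arms_min	n_arms_max	max_forks	forks_is_lower_bound	segments_to_first_fork	genera_count	exceptional
Asteromorpha_koehleri	species	Euryalidae	1	false	none	false	false	5	7	0	false	NA	NA	false
Asteromorpha_tenax	species	Euryalidae	1	false	none	false	false	7	7	0	false	NA	NA	false
Asteroschema_bidwillae	species	Euryalidae	1	false	none	false	false	3	8	0	false	NA	NA	false
Asteroschema_wrighti	species	Euryalidae	1	false	none	false	false	6	6	0	false	NA	NA	false
Astroceras_annulatum	species	Euryalidae	1	false	none	false	false	6	6	0	false	NA	NA	false
Astroceras_kermadecensis	species	Euryalidae	1	false	none	false	false	5	8	0	false	NA	NA	false
Astroceras_nodosum	species	Euryalidae	1	false	none	false	false	6	7	0	false	NA	NA	false
Astroceras_pleiades	species	Euryalidae	1	false	none	false	false	7	7	0	false	NA	NA	false
Astrocharis_ijimai	species	Euryalidae	1	false	none	false	false	4	6	0	false	NA	NA	false
Asteroschema_oligactes	species	Euryalidae	1	false	none	false	false	6	6	0	false	NA	NA	true
Astrobrachion_adhaerens	species	Euryalidae	1	false	none	false	false	6	6	0	false	NA	NA	true
Astroceras_pergamenum	species	Euryalidae	1	false	none	false	false	5	7	0	false	NA	NA	true
Astrocharis_virgo	species	Euryalidae	1	false	none	false	false	5	6	0	false	NA	NA	true
Astrochlamys_sol	species	Gorgonocephalidae	1	false	none	true	false	9	12	0	false	NA	NA	false
Astrochlamys_timoharai	species	Gorgonocephalidae	1	false	none	true	false	11	11	0	false	NA	NA	false
Schizostella_bifurcata	species	Gorgonocephalidae	1	true	distal	true	false	7	7	1	false	NA	NA	false
Astrosierra_microconus	species	Gorgonocephalidae	1	true	distal	true	false	5	6	NA	false	NA	NA	true
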