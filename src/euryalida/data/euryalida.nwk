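(Ophiurida,(Asteronychidae,((Astrocharis,(Astrobrachion,(((Euryale,Trichaster),(Asteromorpha,Astroceras_kermadecensis)),((Sthenocephalus,(Asterostegus,Astroceras_nodosum_group)),(Astroceras,Asteroschema_clade))))),(Astrothamnus,((Astrothrombus,Astroclon),(Astrocrius,(Astroniwa,(((Astrochele,Astrochlamys),(Astrodendrum,Gorgonocephalus)),(Astrothorax,(((Asteroporpa,Astrogomphus),Astrophyton),(Astracme,(Astroboa,(Astrochalcis,(Astrocladus,(Astroglymma,((Astrosierra,Conocladus),Ophiocrene))))))))))))))));
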