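# Reference table of taxon-specific PUFA mass fractions (ug/mg dry weight) in
# littoral benthic macroinvertebrates from 25 Finnish lakes, with the ordinal
# PUFA classes (1-5) assigned to each taxon for ARA, EPA and DHA.
# n_lakes = number of lakes in which the taxon was sampled (per-taxon n sums to 238).
# Missing SD (taxa sampled in a single lake) is encoded as an empty field.
# Note: the Nematoda DHA entry is reported as a range-like token in the source
# summary; it is encoded here as mean 0.0 (not detected), SD missing, class 1.
taxon,n_lakes,mean_ara,sd_ara,class_ara,mean_epa,sd_epa,class_epa,mean_dha,sd_dha,class_dha
Platyhelminthes,5,4.3,1.5,5,9.3,4.0,5,0.9,0.8,5
Nematoda,1,0.6,,2,5.7,,3,0.0,,1
Oligochaeta,16,3.4,1.0,4,7.1,2.2,4,0.4,0.2,5
Hirudinea,12,4.3,1.3,5,5.1,2.6,2,0.2,0.1,4
Gastropoda,8,2.5,1.6,2,2.7,2.4,2,0.3,0.2,5
Bivalvia,2,2.0,0.1,2,0.6,0.0,2,1.1,0.2,5
Heteroptera/Corixidae,5,3.3,1.3,4,12.1,4.7,5,0.3,0.3,5
Odonata/Anisoptera,8,2.6,1.1,2,5.2,5.0,2,0.1,0.1,2
Odonata/Zygoptera,16,5.3,2.4,5,13.2,7.0,5,0.2,0.1,4
Coleoptera/Dytiscidae,7,2.7,1.2,3,7.7,6.4,4,0.2,0.2,4
Coleoptera (others),7,3.9,2.9,5,7.2,3.2,4,0.2,0.2,3
Ephemeroptera,22,3.2,1.8,4,10.2,7.1,5,0.0,0.1,1
Trichoptera,17,2.7,1.6,3,6.5,3.2,3,0.1,0.1,3
Plecoptera,4,2.9,0.7,3,7.4,2.6,4,0.1,0.1,3
Diptera/Ceratopogonidae,13,2.2,0.8,2,7.0,2.7,4,0.1,0.1,3
Diptera/Chironomidae,25,2.7,1.3,3,6.8,3.0,3,0.1,0.1,3
Diptera/Tabanidae,3,1.7,0.7,2,7.1,4.4,4,0.0,0.0,1
Diptera/Sialidae,9,3.1,1.7,4,5.7,3.3,3,0.1,0.1,3
Diptera (others),2,3.5,1.5,4,8.0,2.9,5,0.1,0.1,3
Acari,21,3.2,1.4,4,6.5,3.3,3,0.3,0.3,5
Dictyonidae (Argyroneta aquatica),4,3.1,0.7,4,6.9,0.6,3,0.2,0.2,3
Isopoda (Asellus aquaticus),24,4.0,1.4,5,5.0,2.6,2,0.7,0.2,5
Amphipoda/Gammaridae,5,2.0,1.9,2,3.7,3.5,2,1.0,0.8,5
Amphipoda/Pallasidae,2,4.4,3.0,5,14.4,10.6,5,4.6,3.9,5
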