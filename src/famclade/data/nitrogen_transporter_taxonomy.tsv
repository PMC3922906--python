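abbrev	species	rank
Ac	Aquilegia coerulea	eudicot
Al	Arabidopsis lyrata	eudicot
At	Arabidopsis thaliana	eudicot
Cp	Carica papaya	eudicot
Cs	Cucumis sativus	eudicot
Gm	Glycine max	eudicot
Me	Manihot esculenta	eudicot
Mt	Medicago truncatula	eudicot
Mg	Mimulus guttatus	eudicot
Pt	Populus trichocarpa	eudicot
Prp	Prunus persica	eudicot
Rc	Ricinus communis	eudicot
Vv	Vitis vinifera	eudicot
Bd	Brachypodium distachyon	monocot
Os	Oryza sativa	monocot
Si	Setaria italica	monocot
Sb	Sorghum bicolor	monocot
Zm	Zea mays	monocot
Sm	Selaginella moellendorffii	lycophyte
Pp	Physcomitrella patens	bryophyte
Cr	Chlamydomonas reinhardtii	green_algae
Vc	Volvox carteri	green_algae
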