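family	species	marker	n_correct	n_total
Poaceae	Alopecurus pratensis	matK	0	3
Poaceae	Alopecurus pratensis	rbcLa	0	1
Poaceae	Alopecurus pratensis	trnH-psbA	0	1
Poaceae	Arrhenatherum elatius	matK	1	3
Poaceae	Arrhenatherum elatius	rbcLa	0	2
Poaceae	Arrhenatherum elatius	trnH-psbA	1	1
Poaceae	Cynosurus cristatus	matK	3	3
Poaceae	Cynosurus cristatus	rbcLa	2	3
Poaceae	Cynosurus cristatus	trnH-psbA	3	3
Poaceae	Dactylis glomerata	matK	3	3
Poaceae	Dactylis glomerata	rbcLa	2	3
Poaceae	Dactylis glomerata	trnH-psbA	3	3
Poaceae	Festuca pratensis	matK	2	3
Poaceae	Festuca pratensis	rbcLa	0	3
Poaceae	Festuca pratensis	trnH-psbA	1	3
Poaceae	Festuca rubra	matK	1	3
Poaceae	Festuca rubra	rbcLa	3	3
Poaceae	Festuca rubra	trnH-psbA	2	3
Poaceae	Lolium multiflorum	matK	0	3
Poaceae	Lolium multiflorum	rbcLa	2	3
Poaceae	Lolium multiflorum	trnH-psbA	1	3
Poaceae	Lolium perenne	matK	2	3
Poaceae	Lolium perenne	rbcLa	0	3
Poaceae	Lolium perenne	trnH-psbA	2	3
Poaceae	Phleum pratense	matK	1	2
Poaceae	Phleum pratense	rbcLa	1	2
Poaceae	Phleum pratense	trnH-psbA	1	1
Poaceae	Poa pratensis	matK	0	3
Poaceae	Poa pratensis	rbcLa	1	2
Poaceae	Poa pratensis	trnH-psbA	0	2
Poaceae	Trisetum flavescens	matK	2	3
Poaceae	Trisetum flavescens	rbcLa	2	3
Poaceae	Trisetum flavescens	trnH-psbA	3	3
Fabaceae	Lotus corniculatus	matK	1	3
Fabaceae	Lotus corniculatus	rbcLa	3	3
Fabaceae	Lotus corniculatus	trnH-psbA	3	3
Fabaceae	Medicago sativa	matK	2	3
Fabaceae	Medicago sativa	rbcLa	3	3
Fabaceae	Medicago sativa	trnH-psbA	3	3
Fabaceae	Onobrychis viciifolia	matK	2	3
Fabaceae	Onobrychis viciifolia	rbcLa	3	3
Fabaceae	Onobrychis viciifolia	trnH-psbA	3	3
Fabaceae	Trifolium pratense	matK	2	2
Fabaceae	Trifolium pratense	rbcLa	2	3
Fabaceae	Trifolium pratense	trnH-psbA	3	3
Fabaceae	Trifolium repens	matK	1	3
Fabaceae	Trifolium repens	rbcLa	3	3
Fabaceae	Trifolium repens	trnH-psbA	3	3
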