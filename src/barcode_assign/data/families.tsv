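species	family
Alopecurus pratensis	Poaceae
Arrhenatherum elatius	Poaceae
Cynosurus cristatus	Poaceae
Dactylis glomerata	Poaceae
Festuca pratensis	Poaceae
Festuca rubra	Poaceae
Lolium multiflorum	Poaceae
Lolium perenne	Poaceae
Lotus corniculatus	Fabaceae
Medicago sativa	Fabaceae
Onobrychis viciifolia	Fabaceae
Phleum pratense	Poaceae
Poa pratensis	Poaceae
Trifolium pratense	Fabaceae
Trifolium repens	Fabaceae
Trisetum flavescens	Poaceae
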