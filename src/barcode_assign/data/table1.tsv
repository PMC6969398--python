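record_id	species	cultivar	marker	length	n_count	failed
SWFRG013-19	Alopecurus pratensis	Alko	rbcLa	0	0	1
SWFRG013-19	Alopecurus pratensis	Alko	matK	838	0	0
SWFRG013-19	Alopecurus pratensis	Alko	trnH-psbA	0	0	1
SWFRG014-19	Alopecurus pratensis	Alopex	rbcLa	0	0	1
SWFRG014-19	Alopecurus pratensis	Alopex	matK	663	0	0
SWFRG014-19	Alopecurus pratensis	Alopex	trnH-psbA	0	0	1
SWFRG029-19	Alopecurus pratensis	Alopex	rbcLa	552	0	0
SWFRG029-19	Alopecurus pratensis	Alopex	matK	185	0	0
SWFRG029-19	Alopecurus pratensis	Alopex	trnH-psbA	569	0	0
SWFRG015-19	Arrhenatherum elatius	Arone	rbcLa	549	0	0
SWFRG015-19	Arrhenatherum elatius	Arone	matK	436	0	0
SWFRG015-19	Arrhenatherum elatius	Arone	trnH-psbA	512	0	0
SWFRG016-19	Arrhenatherum elatius	Median	rbcLa	550	0	0
SWFRG016-19	Arrhenatherum elatius	Median	matK	610	0	0
SWFRG016-19	Arrhenatherum elatius	Median	trnH-psbA	0	0	1
SWFRG031-19	Arrhenatherum elatius	Median	rbcLa	0	0	1
SWFRG031-19	Arrhenatherum elatius	Median	matK	825	0	0
SWFRG031-19	Arrhenatherum elatius	Median	trnH-psbA	0	0	1
SWFRG030-19	Cynosurus cristatus	Cresta	rbcLa	541	0	0
SWFRG030-19	Cynosurus cristatus	Cresta	matK	513	0	0
SWFRG030-19	Cynosurus cristatus	Cresta	trnH-psbA	466	0	0
SWFRG045-19	Cynosurus cristatus	Lena	rbcLa	585	0	0
SWFRG045-19	Cynosurus cristatus	Lena	matK	531	0	0
SWFRG045-19	Cynosurus cristatus	Lena	trnH-psbA	564	0	0
SWFRG046-19	Cynosurus cristatus	Roznovska	rbcLa	529	0	0
SWFRG046-19	Cynosurus cristatus	Roznovska	matK	870	0	0
SWFRG046-19	Cynosurus cristatus	Roznovska	trnH-psbA	569	0	0
SWFRG001-19	Dactylis glomerata	Barexcel	rbcLa	577	0	0
SWFRG001-19	Dactylis glomerata	Barexcel	matK	640	0	0
SWFRG001-19	Dactylis glomerata	Barexcel	trnH-psbA	519	0	0
SWFRG002-19	Dactylis glomerata	Brennus	rbcLa	546	0	0
SWFRG002-19	Dactylis glomerata	Brennus	matK	865	13	0
SWFRG002-19	Dactylis glomerata	Brennus	trnH-psbA	576	0	0
SWFRG017-19	Dactylis glomerata	Reda	rbcLa	534	0	0
SWFRG017-19	Dactylis glomerata	Reda	matK	866	13	0
SWFRG017-19	Dactylis glomerata	Reda	trnH-psbA	561	0	0
SWFRG003-19	Festuca pratensis	Cosmolit	rbcLa	547	0	0
SWFRG003-19	Festuca pratensis	Cosmolit	matK	579	0	0
SWFRG003-19	Festuca pratensis	Cosmolit	trnH-psbA	558	0	0
SWFRG004-19	Festuca pratensis	Paradisia	rbcLa	549	0	0
SWFRG004-19	Festuca pratensis	Paradisia	matK	888	7	0
SWFRG004-19	Festuca pratensis	Paradisia	trnH-psbA	566	0	0
SWFRG019-19	Festuca pratensis	Pradel	rbcLa	552	0	0
SWFRG019-19	Festuca pratensis	Pradel	matK	590	0	0
SWFRG019-19	Festuca pratensis	Pradel	trnH-psbA	553	0	0
SWFRG007-19	Festuca rubra	Echo	rbcLa	559	0	0
SWFRG007-19	Festuca rubra	Echo	matK	886	3	0
SWFRG007-19	Festuca rubra	Echo	trnH-psbA	274	21	0
SWFRG008-19	Festuca rubra	Pran Solas	rbcLa	588	0	0
SWFRG008-19	Festuca rubra	Pran Solas	matK	869	0	0
SWFRG008-19	Festuca rubra	Pran Solas	trnH-psbA	570	0	0
SWFRG023-19	Festuca rubra	Roland	rbcLa	558	0	0
SWFRG023-19	Festuca rubra	Roland	matK	543	0	0
SWFRG023-19	Festuca rubra	Roland	trnH-psbA	594	0	0
SWFRG005-19	Lolium multiflorum	Axis	rbcLa	581	0	0
SWFRG005-19	Lolium multiflorum	Axis	matK	874	0	0
SWFRG005-19	Lolium multiflorum	Axis	trnH-psbA	551	0	0
SWFRG006-19	Lolium multiflorum	Caribu	rbcLa	577	0	0
SWFRG006-19	Lolium multiflorum	Caribu	matK	884	8	0
SWFRG006-19	Lolium multiflorum	Caribu	trnH-psbA	567	7	0
SWFRG021-19	Lolium multiflorum	Zebra	rbcLa	571	0	0
SWFRG021-19	Lolium multiflorum	Zebra	matK	586	0	0
SWFRG021-19	Lolium multiflorum	Zebra	trnH-psbA	551	0	0
SWFRG009-19	Lolium perenne	Arara	rbcLa	547	0	0
SWFRG009-19	Lolium perenne	Arara	matK	883	3	0
SWFRG009-19	Lolium perenne	Arara	trnH-psbA	539	5	0
SWFRG010-19	Lolium perenne	Arvella	rbcLa	582	0	0
SWFRG010-19	Lolium perenne	Arvella	matK	481	0	0
SWFRG010-19	Lolium perenne	Arvella	trnH-psbA	567	15	0
SWFRG025-19	Lolium perenne	Lipresso	rbcLa	488	0	0
SWFRG025-19	Lolium perenne	Lipresso	matK	835	0	0
SWFRG025-19	Lolium perenne	Lipresso	trnH-psbA	614	0	0
SWFRG024-19	Lotus corniculatus	Lotar	rbcLa	544	0	0
SWFRG024-19	Lotus corniculatus	Lotar	matK	399	0	0
SWFRG024-19	Lotus corniculatus	Lotar	trnH-psbA	294	0	0
SWFRG039-19	Lotus corniculatus	Lotar	rbcLa	548	0	0
SWFRG039-19	Lotus corniculatus	Lotar	matK	509	0	0
SWFRG039-19	Lotus corniculatus	Lotar	trnH-psbA	414	0	0
SWFRG040-19	Lotus corniculatus	Polom	rbcLa	502	0	0
SWFRG040-19	Lotus corniculatus	Polom	matK	702	0	0
SWFRG040-19	Lotus corniculatus	Polom	trnH-psbA	412	0	0
SWFRG022-19	Medicago sativa	Artemis	rbcLa	580	0	0
SWFRG022-19	Medicago sativa	Artemis	matK	410	0	0
SWFRG022-19	Medicago sativa	Artemis	trnH-psbA	268	14	0
SWFRG037-19	Medicago sativa	Catera	rbcLa	526	0	0
SWFRG037-19	Medicago sativa	Catera	matK	435	0	0
SWFRG037-19	Medicago sativa	Catera	trnH-psbA	438	3	0
SWFRG038-19	Medicago sativa	Sanditi	rbcLa	548	0	0
SWFRG038-19	Medicago sativa	Sanditi	matK	432	0	0
SWFRG038-19	Medicago sativa	Sanditi	trnH-psbA	445	2	0
SWFRG028-19	Onobrychis viciifolia	Perdix	rbcLa	550	0	0
SWFRG028-19	Onobrychis viciifolia	Perdix	matK	576	0	0
SWFRG028-19	Onobrychis viciifolia	Perdix	trnH-psbA	289	0	0
SWFRG043-19	Onobrychis viciifolia	Perly	rbcLa	582	0	0
SWFRG043-19	Onobrychis viciifolia	Perly	matK	627	0	0
SWFRG043-19	Onobrychis viciifolia	Perly	trnH-psbA	284	0	0
SWFRG044-19	Onobrychis viciifolia	Visnovsky	rbcLa	543	0	0
SWFRG044-19	Onobrychis viciifolia	Visnovsky	matK	694	10	0
SWFRG044-19	Onobrychis viciifolia	Visnovsky	trnH-psbA	287	0	0
SWFRG032-19	Phleum pratense	Anjo	rbcLa	540	0	0
SWFRG032-19	Phleum pratense	Anjo	matK	0	0	1
SWFRG032-19	Phleum pratense	Anjo	trnH-psbA	0	0	1
SWFRG047-19	Phleum pratense	Tiller	rbcLa	576	0	0
SWFRG047-19	Phleum pratense	Tiller	matK	527	5	0
SWFRG047-19	Phleum pratense	Tiller	trnH-psbA	584	0	0
SWFRG048-19	Phleum pratense	Toro	rbcLa	0	0	1
SWFRG048-19	Phleum pratense	Toro	matK	516	1	0
SWFRG048-19	Phleum pratense	Toro	trnH-psbA	0	0	1
SWFRG011-19	Poa pratensis	Likollo	rbcLa	470	0	0
SWFRG011-19	Poa pratensis	Likollo	matK	865	0	0
SWFRG011-19	Poa pratensis	Likollo	trnH-psbA	540	0	0
SWFRG012-19	Poa pratensis	Nixe	rbcLa	571	0	0
SWFRG012-19	Poa pratensis	Nixe	matK	868	0	0
SWFRG012-19	Poa pratensis	Nixe	trnH-psbA	576	0	0
SWFRG027-19	Poa pratensis	Tommy	rbcLa	0	0	1
SWFRG027-19	Poa pratensis	Tommy	matK	489	0	0
SWFRG027-19	Poa pratensis	Tommy	trnH-psbA	0	0	1
SWFRG020-19	Trifolium pratense	Bonus	rbcLa	549	0	0
SWFRG020-19	Trifolium pratense	Bonus	matK	0	0	1
SWFRG020-19	Trifolium pratense	Bonus	trnH-psbA	410	0	0
SWFRG035-19	Trifolium pratense	Diplomat	rbcLa	564	0	0
SWFRG035-19	Trifolium pratense	Diplomat	matK	556	0	0
SWFRG035-19	Trifolium pratense	Diplomat	trnH-psbA	485	0	0
SWFRG036-19	Trifolium pratense	Pavo	rbcLa	514	0	0
SWFRG036-19	Trifolium pratense	Pavo	matK	430	0	0
SWFRG036-19	Trifolium pratense	Pavo	trnH-psbA	496	0	0
SWFRG026-19	Trifolium repens	Beaumont	rbcLa	550	0	0
SWFRG026-19	Trifolium repens	Beaumont	matK	419	0	0
SWFRG026-19	Trifolium repens	Beaumont	trnH-psbA	448	0	0
SWFRG041-19	Trifolium repens	Bombus	rbcLa	579	0	0
SWFRG041-19	Trifolium repens	Bombus	matK	481	0	0
SWFRG041-19	Trifolium repens	Bombus	trnH-psbA	471	0	0
SWFRG042-19	Trifolium repens	Hebe	rbcLa	571	0	0
SWFRG042-19	Trifolium repens	Hebe	matK	444	0	0
SWFRG042-19	Trifolium repens	Hebe	trnH-psbA	447	0	0
SWFRG018-19	Trisetum flavescens	Gunther	rbcLa	504	0	0
SWFRG018-19	Trisetum flavescens	Gunther	matK	859	6	0
SWFRG018-19	Trisetum flavescens	Gunther	trnH-psbA	570	0	0
SWFRG033-19	Trisetum flavescens	Gunther	rbcLa	575	0	0
SWFRG033-19	Trisetum flavescens	Gunther	matK	586	4	0
SWFRG033-19	Trisetum flavescens	Gunther	trnH-psbA	571	0	0
SWFRG034-19	Trisetum flavescens	Trisett51	rbcLa	558	0	0
SWFRG034-19	Trisetum flavescens	Trisett51	matK	887	4	0
SWFRG034-19	Trisetum flavescens	Trisett51	trnH-psbA	568	0	0
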