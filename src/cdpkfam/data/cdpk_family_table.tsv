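name	previous_name	accession	alternative_splicing	cds_length_nt	aa_length	mw_kda	octapeptide	myristoylation	n_ef_hands
ZmCPK1	-	GRMZM2G314396_T01	-	1644	547	604	MGNACSGA	Yes	4
ZmCPK2	ZmCDPK1	D84408	-	1479	492	547	MRRGGAGA	No	4
ZmCPK3	ZmCK1	GRMZM2G321239_T01	-	1671	556	612	MGNACGGA	Yes	4
ZmCPK4	ZmCDPK7	D87042	-	1665	554	616	MGNACGGA	Yes	4
ZmCPK5	-	GRMZM2G081310_T01	3	1689	562	619	MGNTCGVT	Yes	4
ZmCPK6	-	GRMZM2G347047_T01	-	1467	488	539	MGGHQLHL	No	4
ZmCPK7	-	GRMZM2G032852_T02	3	1635	544	617	MGNQCPNG	No	1
ZmCPK8	-	GRMZM2G027351_T01	2	1755	584	641	MGNTCVGP	No	4
ZmCPK9	-	GRMZM2G121228_T01	-	1743	580	637	MGNTCVGP	No	4
ZmCPK10	-	GRMZM2G353957_T01	-	1941	646	717	MGNVCVGP	No	4
ZmCPK11	-	GRMZM2G028926_T01	-	1827	608	664	MGNTCVGP	No	4
ZmCPK12	-	GRMZM2G320506_T01	-	1863	620	677	MGNTCVGP	No	4
ZmCPK13	ZmCDPK10	AJ007366	-	1920	639	695	MGNTCVGP	No	4
ZmCPK14	-	GRMZM2G035843_T01	-	1527	508	565	MQPDPSGN	No	4
ZmCPK15	ZmCDPK11	GRMZM2G047486_T01	5	1533	510	566	MQPDPSGN	No	4
ZmCPK16	-	GRMZM2G347226_T01	2	1548	515	568	MQPDPQGS	No	4
ZmCPK17	-	GRMZM2G463464_T01	2	1548	515	568	MQPDPQGP	No	4
ZmCPK18	-	GRMZM2G167276_T01	-	1533	510	562	MGNCCPGS	No	4
ZmCPK19	-	GRMZM2G340224_T01	2	1842	613	675	MRPSVSMI	No	4
ZmCPK20	-	GRMZM2G365815_T01	-	1659	552	600	MGQCCSKG	Yes	4
ZmCPK21	-	GRMZM2G472311_T01	-	1746	581	634	MGQCCSKG	Yes	4
ZmCPK22	-	GRMZM2G058305_T01	3	1620	539	607	MGGRASRH	Yes	4
ZmCPK23	-	GRMZM2G025387_T01	3	1593	530	599	MGNRASRH	Yes	4
ZmCPK24	-	GRMZM5G856738_T02	3	1383	460	525	MEDVKATY	No	4
ZmCPK25	-	GRMZM2G112057_T01	-	1620	539	610	MGNCFTRK	Yes	4
ZmCPK26	-	GRMZM2G154489_T01	2	1596	531	594	MGQCCSRA	Yes	4
ZmCPK27	ZmCDPK2	ZMU28376	-	1542	513	581	MVMAILTR	No	4
ZmCPK28	ZmCDPK9	GRMZM2G168706_T01	4	1596	531	594	MGQCCSRA	Yes	4
ZmCPK29	-	GRMZM2G030673_T01	-	1626	541	605	MGNCCRSP	No	3
ZmCPK30	-	GRMZM2G088361_T01	-	1623	540	602	MGNCCRSP	No	3
ZmCPK31	-	GRMZM2G311220_T01	3	1611	536	602	MGNCCRSP	No	3
ZmCPK32	-	GRMZM2G332660_T01	-	1707	568	628	MGGCYSAF	Yes	4
ZmCPK33	-	AC2100134_FGT014	-	1617	538	604	MGNCCAAP	Yes	4
ZmCPK34	-	GRMZM2G104125_T01	-	1608	535	603	MGNCCATP	Yes	4
ZmCPK35	-	AC2338711_FGT003	-	1620	539	608	MGNCCVTP	No	4
ZmCPK36	-	GRMZM2G028086_T01	2	1620	539	608	MGNCCVTP	No	4
ZmCPK37	-	GRMZM2G099425_T01	-	1620	539	608	MGNCCVTP	No	4
ZmCPK38	-	GRMZM2G365035_T01	-	1539	512	575	MGLCSSST	Yes	4
ZmCPK39	-	GRMZM2G157068_T01	3	1569	522	585	MGACFSSA	Yes	4
ZmCPK40	-	GRMZM2G053868_T01	3	1569	522	585	MGACFSSA	Yes	4
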