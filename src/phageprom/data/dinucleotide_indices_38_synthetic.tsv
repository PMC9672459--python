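# SYNTHETIC stand-in for a 38-index dinucleotide physicochemical reference
# set (the curated published list is not redistributable here). Values are
# deterministic pseudo-random draws (seed 20221104), standardized before use;
# they exercise the identical code path as a curated table. Supply your own
# PhysicochemicalIndexSet for biologically meaningful indices.
dinucleotide	syn01	syn02	syn03	syn04	syn05	syn06	syn07	syn08	syn09	syn10	syn11	syn12	syn13	syn14	syn15	syn16	syn17	syn18	syn19	syn20	syn21	syn22	syn23	syn24	syn25	syn26	syn27	syn28	syn29	syn30	syn31	syn32	syn33	syn34	syn35	syn36	syn37	syn38
AA	-0.3369	0.8805	-0.7085	-0.7859	-1.5341	0.4423	-0.0188	0.7473	-2.6921	0.3692	-0.9840	1.6663	0.4012	-0.5102	0.5534	-0.2567	-0.3490	0.1774	-1.1867	-0.7040	1.0277	0.6308	1.7564	0.9264	0.1249	-0.5659	-0.6673	0.9222	-0.2210	1.7152	-0.1619	-0.3530	0.5512	1.4198	0.3444	1.5324	-0.5662	0.1199
AC	0.0879	1.7635	-1.5364	-1.1616	0.0810	-0.2783	1.0799	-1.3989	-0.2717	-1.3466	-1.6608	0.2029	-1.1208	1.1220	-0.2757	2.2619	-1.3986	-0.3551	0.3161	-0.7953	1.7478	0.6100	-0.1722	0.3730	-0.8020	0.3042	0.9395	0.7242	0.1595	1.1058	1.7397	1.7820	1.0216	0.9269	-1.0122	0.1236	-0.7697	0.3971
AG	0.9932	0.6181	-0.4971	0.8477	-1.7013	0.6993	0.4365	-0.0829	0.7610	-0.9385	-0.2180	0.3272	0.0700	-0.9704	-0.6478	-0.7577	0.1599	0.3357	-1.3273	0.3631	1.1828	1.3065	-0.5311	0.3016	0.0923	-0.7453	1.6223	-0.0294	0.5547	2.0786	-0.7392	-0.1855	0.0957	0.2172	2.1997	1.8010	0.7745	0.1892
AT	1.9973	-1.6967	-1.2456	0.1214	-0.3169	-0.6452	-0.4886	-0.5026	-0.5704	1.4285	-0.0934	0.6676	1.1567	0.5807	-0.6775	-0.1419	0.8580	0.6803	0.1473	-0.5209	-0.1699	-1.4709	0.2345	-0.5889	0.3255	-1.0114	-1.4230	-0.1900	0.4127	0.2791	0.7812	1.0752	0.4139	0.8169	1.6081	0.3979	-0.2163	1.2203
CA	-1.0500	-0.7226	0.8687	1.7590	0.5436	-0.4992	-1.0886	1.5309	-0.7003	-0.7812	-1.1565	-1.1769	-0.6404	0.3565	0.6213	0.7366	1.2897	-0.1684	0.5099	0.4443	-0.4352	1.2842	1.3980	0.1590	-1.9845	-1.5291	0.3016	-0.4632	1.4045	-0.3184	0.5419	-0.1334	-1.0145	1.2674	0.0761	0.5536	-0.6657	0.2383
CC	-0.6468	-0.2265	-2.9598	1.8946	-0.2791	-0.5293	-0.3374	-1.4939	-0.1074	0.8474	0.6100	0.3462	-0.5750	-0.2276	-0.6628	1.5599	0.1411	-0.1391	0.2564	0.9693	0.2321	-0.9536	0.1418	0.8128	-0.5385	0.1106	-0.6826	1.5282	-0.6603	0.1849	0.1758	-0.3679	0.2959	0.1162	0.6436	-0.3681	1.6432	0.7323
CG	-0.0093	0.6875	-0.4502	-0.4900	-1.4393	0.2899	-0.1766	-0.1860	0.0804	1.6026	1.3338	1.0925	-0.7600	0.9035	-1.0852	-0.1679	-1.1215	0.7434	1.1751	-0.5942	-0.5142	0.7240	-0.7229	-0.2217	-0.3930	-0.8559	-1.0312	-1.3182	-0.1661	-0.3512	0.5019	-0.0898	1.9099	1.7166	-0.6076	1.0961	1.2455	-0.0111
CT	-1.6713	1.8598	0.9761	-0.3452	-0.3310	1.5680	0.2425	-0.6714	-0.2821	0.2501	-1.4200	-0.1961	1.8205	-0.3379	0.2179	-0.5938	1.6715	0.6168	-0.6793	0.2482	0.9319	1.3922	-0.1603	0.6863	-1.7338	1.2020	-0.7558	-0.0938	-0.8856	0.1377	-1.5470	0.7558	-1.3350	-0.4118	-0.9174	-0.4063	1.2600	-0.8062
GA	0.4203	0.7576	0.0929	0.9699	0.4813	0.0058	0.7167	-0.7978	-0.6229	-0.4528	-0.5027	-0.1504	0.9379	0.4038	-0.0576	-0.0478	2.2133	-0.0369	0.1365	0.6513	-0.7579	0.5906	0.4970	0.1812	-0.0088	-0.3761	-0.4319	-0.2552	0.5554	1.0439	0.2880	0.6668	-1.5161	-0.4116	0.2811	0.1724	0.4844	0.2294
GC	0.4324	0.1628	-1.2186	-0.7678	0.9060	-0.7055	-0.0430	-0.0333	0.6749	-0.1033	-0.1538	-0.6980	-1.1489	1.1551	-0.9585	0.6231	-0.5081	-0.6875	-0.5638	-0.6211	-0.1265	0.7916	-0.1795	0.8016	1.9074	0.2330	2.2031	-1.6052	2.4908	0.3207	-0.0565	-0.8419	0.3552	0.4611	-0.4142	0.2950	-0.7252	1.1942
GG	0.4654	1.8943	0.0670	-0.6689	-1.0596	0.4186	-1.5227	0.8160	-0.2183	-0.0332	2.9760	0.9389	0.0053	-0.2714	1.1551	0.7747	-0.4000	0.6029	1.2553	0.7361	-0.5851	-1.3550	0.0085	-1.7753	-0.3338	-0.7139	0.0849	0.6406	-1.1297	-0.1931	-0.4783	1.4017	1.0523	-0.2691	0.7600	-0.1556	-1.4916	0.2421
GT	-0.5527	0.4376	0.9833	-0.4055	-1.4698	-1.3609	0.1334	-0.8667	-1.3624	1.5936	1.0313	0.5664	1.9773	0.1429	-1.0335	-1.9238	1.9074	1.1445	0.2640	-0.0655	-0.9513	0.3129	0.8145	0.8763	0.1534	1.8082	-0.8484	0.6191	0.5225	-1.2045	-0.7831	-0.2218	-0.1502	0.8652	-1.2028	0.2692	-0.1845	-0.3091
TA	0.4264	0.2657	0.7328	0.1864	0.5098	-1.7342	0.9787	0.8227	-0.2456	-1.4465	0.8112	-0.5458	1.4018	0.1394	-0.2843	-1.9364	-1.4687	1.7051	1.0483	0.1295	2.1297	1.8642	-0.2119	-0.9210	0.6349	-0.3287	-0.2727	-0.1006	-0.5959	0.0919	1.7099	-0.3419	-0.6717	-0.4504	0.9985	-1.5106	-0.3733	0.9293
TC	-1.2972	-1.4855	-0.1672	0.4550	1.6194	0.7045	1.1073	1.3637	-0.1545	-0.6064	-0.9132	-1.6695	-0.3231	1.6370	1.2715	-0.0982	0.2666	-1.4415	1.0147	0.8318	1.3850	-0.0841	-0.1025	0.0451	0.4042	1.3454	1.1094	-0.0470	-0.0322	2.1882	1.7019	-0.4413	0.0425	-0.9148	0.9135	0.5777	-0.5069	-1.5097
TG	0.8737	-0.6233	1.4663	0.4819	-0.8442	1.0703	1.1564	0.4814	0.0133	0.8357	1.0283	-0.3687	-0.2611	0.1789	-1.2156	-0.6175	-1.4249	-0.7901	2.0746	0.5544	-0.1912	-1.1848	-0.8974	0.2013	-0.2313	0.9023	-0.0772	0.2685	0.7910	1.4912	-0.5114	-0.4273	-0.7908	1.4996	-0.3436	-0.5294	2.2677	-0.3230
TT	-0.5366	0.6451	-1.2188	1.0618	0.6531	0.5454	-0.8522	-1.8361	1.0146	-0.3387	-1.1496	1.0023	0.9564	1.2600	-0.9729	0.3900	-0.0781	-1.5083	-0.1157	-1.0732	0.2774	1.9796	-0.1450	-0.2197	1.0535	0.3060	0.1832	-0.3645	-0.8243	0.7353	-0.6575	0.1739	-1.3983	-0.6423	0.4596	0.2088	-1.1277	-0.3169
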