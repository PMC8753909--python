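variant_id	chrom	pos	effect_allele	other_allele	weight	freq
snp001	5	235105	G	A	0.0733	0.3534
snp002	3	243062	T	C	0.0762	0.7442
snp003	7	976736	A	G	0.0783	0.5355
snp004	5	1318855	A	C	0.0152	0.8886
snp005	17	1519119	C	T	0.0758	0.2562
snp006	11	1630763	T	C	0.0395	0.8729
snp007	6	1750635	T	C	0.0485	0.8058
snp008	20	2620926	T	G	0.0605	0.7181
snp009	20	3293029	T	C	0.0381	0.3227
snp010	7	3984557	A	G	0.038	0.4264
snp011	18	4564876	A	C	0.0255	0.2652
snp012	8	4959117	T	C	0.0736	0.1818
snp013	20	5262537	A	G	0.0453	0.6286
snp014	15	6057675	A	G	0.0276	0.6589
snp015	6	6539602	G	T	0.059	0.2879
snp016	1	7209249	A	G	0.039	0.4614
snp017	8	7895483	G	A	0.0516	0.1186
snp018	22	8633418	C	A	0.0196	0.3641
snp019	18	9105908	T	G	0.0172	0.6141
snp020	6	9577518	T	C	0.0712	0.5917
snp021	8	10116491	A	C	0.0797	0.9132
snp022	12	10755593	T	G	0.0473	0.6559
snp023	18	11522445	G	A	0.0751	0.3262
snp024	22	12330712	G	A	0.0356	0.6929
snp025	21	13068815	G	A	0.0278	0.1501
snp026	22	13790753	A	C	0.0515	0.8165
snp027	9	14678258	T	C	0.0283	0.6943
snp028	4	15395566	G	T	0.0752	0.5336
snp029	19	15958544	C	A	0.0445	0.0726
snp030	10	16558992	G	A	0.0122	0.2958
snp031	20	17250746	T	G	0.05	0.3086
snp032	3	17492827	T	G	0.0286	0.0605
snp033	3	17702539	T	G	0.0583	0.2207
snp034	16	17782789	G	A	0.0448	0.7976
snp035	17	18502281	A	C	0.0776	0.4882
snp036	6	18606882	A	C	0.0331	0.6577
snp037	20	19270631	G	A	0.0657	0.612
snp038	1	19711752	T	C	0.0216	0.3159
snp039	1	19994355	G	T	0.0454	0.4401
snp040	19	20593279	A	C	0.0348	0.8061
snp041	7	21211436	G	T	0.0316	0.0669
snp042	4	21945736	G	A	0.0295	0.8656
snp043	14	22531327	G	A	0.0276	0.1894
snp044	17	23279566	C	T	0.0491	0.2762
snp045	19	23758620	G	T	0.0601	0.5542
snp046	11	24263997	G	A	0.0638	0.1654
snp047	2	24328588	G	A	0.0627	0.5154
snp048	4	24866624	A	G	0.0424	0.4217
snp049	2	25125505	A	G	0.0244	0.3762
snp050	7	25471784	G	A	0.0788	0.3312
snp051	15	25624460	C	A	0.0577	0.8907
snp052	17	25994338	C	T	0.0111	0.6866
snp053	21	26738182	G	T	0.0797	0.1614
snp054	10	26806293	T	G	0.0311	0.3562
snp055	8	27167965	A	G	0.0504	0.6416
snp056	10	27998008	T	C	0.0383	0.3173
snp057	5	28561151	T	G	0.0428	0.4274
snp058	16	29400639	C	A	0.0645	0.1198
snp059	18	29644467	A	G	0.0389	0.8839
snp060	8	29768511	G	A	0.0513	0.6294
snp061	20	30567219	A	G	0.0629	0.7557
snp062	11	30988097	G	T	0.0678	0.5301
snp063	1	31192052	G	A	0.0673	0.8718
snp064	3	31249989	C	A	0.0718	0.4442
snp065	11	31319125	A	C	0.0751	0.1733
snp066	14	32206072	A	C	0.056	0.5132
snp067	12	32840536	T	C	0.0127	0.1463
snp068	13	32881523	T	C	0.0616	0.5389
snp069	20	33399487	T	G	0.0411	0.3297
snp070	8	33729079	G	T	0.0266	0.6391
snp071	10	34271818	C	A	0.0653	0.3907
snp072	19	34426168	T	C	0.0538	0.0565
snp073	1	35093592	C	T	0.0363	0.2421
snp074	9	35507997	C	T	0.014	0.8445
snp075	18	36350923	A	C	0.0797	0.568
snp076	1	36389445	C	A	0.0395	0.7211
snp077	22	37248308	G	T	0.0371	0.3354
snp078	11	37959190	G	T	0.0467	0.0998
snp079	8	38577869	T	G	0.0514	0.8271
snp080	3	39317910	T	C	0.0253	0.1015
snp081	17	40107707	A	G	0.0409	0.7664
snp082	22	40800009	T	G	0.0485	0.7335
snp083	3	41627065	G	A	0.0219	0.3064
snp084	15	42112077	A	G	0.0396	0.4251
snp085	4	42994280	T	G	0.0192	0.7822
snp086	7	43213196	T	C	0.0268	0.4887
snp087	22	43394407	T	G	0.0392	0.9413
snp088	15	43901998	T	C	0.0486	0.1462
snp089	16	44792483	T	G	0.038	0.6145
snp090	22	45195856	T	G	0.0262	0.1275
snp091	5	45994886	A	C	0.0774	0.9381
snp092	11	46381743	A	C	0.0678	0.5425
snp093	9	46533910	C	A	0.07	0.7584
snp094	11	47365068	A	C	0.0623	0.3721
snp095	4	47822420	T	G	0.0167	0.423
snp096	3	48557403	T	G	0.0604	0.1807
snp097	13	49210520	A	C	0.0116	0.3706
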