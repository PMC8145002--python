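marker_id	chrom	start	end	repeat_unit	reference_length
m000	chr1	2421214	2421224	A	10
m001	chr2	2342525	2342536	T	11
m002	chr3	2873570	2873594	AC	12
m003	chr4	2059274	2059300	AG	13
m004	chr5	2134221	2134249	AT	14
m005	chr6	2159264	2159294	CA	15
m006	chr7	2416176	2416192	A	16
m007	chr8	2093485	2093502	T	17
m008	chr9	2240260	2240296	AC	18
m009	chr10	2823932	2823970	AG	19
m010	chr11	2848439	2848479	AT	20
m011	chr12	2827253	2827295	CA	21
m012	chr13	2847996	2848018	A	22
m013	chr14	2159445	2159468	T	23
m014	chr15	2718480	2718528	AC	24
m015	chr16	2382180	2382200	AG	10
m016	chr17	2771515	2771537	AT	11
m017	chr18	2919658	2919682	CA	12
m018	chr19	2585175	2585188	A	13
m019	chr20	2864410	2864424	T	14
m020	chr21	2010915	2010945	AC	15
m021	chr22	2654013	2654045	AG	16
m022	chr1	5808124	5808158	AT	17
m023	chr2	5937923	5937959	CA	18
m024	chr3	6142301	6142320	A	19
m025	chr4	5953467	5953487	T	20
m026	chr5	6266636	6266678	AC	21
m027	chr6	5996040	5996084	AG	22
m028	chr7	6482174	6482220	AT	23
m029	chr8	6220964	6221012	CA	24
m030	chr9	6093475	6093485	A	10
m031	chr10	5542450	5542461	T	11
m032	chr11	6228367	6228391	AC	12
m033	chr12	5892715	5892741	AG	13
m034	chr13	6413909	6413937	AT	14
m035	chr14	6494353	6494383	CA	15
m036	chr15	5984312	5984328	A	16
m037	chr16	6124444	6124461	T	17
m038	chr17	6467673	6467709	AC	18
m039	chr18	6269569	6269607	AG	19
m040	chr19	5822747	5822787	AT	20
m041	chr20	6356746	6356788	CA	21
m042	chr21	5536395	5536417	A	22
m043	chr22	5838484	5838507	T	23
m044	chr1	9098197	9098245	AC	24
m045	chr2	9416952	9416972	AG	10
m046	chr3	9922750	9922772	AT	11
m047	chr4	9799522	9799546	CA	12
m048	chr5	9184637	9184650	A	13
m049	chr6	9730080	9730094	T	14
m050	chr7	9326539	9326569	AC	15
m051	chr8	9448526	9448558	AG	16
m052	chr9	9478158	9478192	AT	17
m053	chr10	9514503	9514539	CA	18
m054	chr11	9960020	9960039	A	19
m055	chr12	9890748	9890768	T	20
m056	chr13	9362088	9362130	AC	21
m057	chr14	9879945	9879989	AG	22
m058	chr15	9676748	9676794	AT	23
m059	chr16	9683443	9683491	CA	24
m060	chr17	9849859	9849869	A	10
m061	chr18	9362732	9362743	T	11
m062	chr19	9167014	9167038	AC	12
m063	chr20	9700676	9700702	AG	13
m064	chr21	9804050	9804078	AT	14
m065	chr22	9523010	9523040	CA	15
m066	chr1	12955362	12955378	A	16
m067	chr2	12947592	12947609	T	17
m068	chr3	13181369	13181405	AC	18
m069	chr4	12967896	12967934	AG	19
m070	chr5	12897658	12897698	AT	20
m071	chr6	12867089	12867131	CA	21
m072	chr7	13475839	13475861	A	22
m073	chr8	12828483	12828506	T	23
m074	chr9	12959274	12959322	AC	24
m075	chr10	13129492	13129512	AG	10
m076	chr11	12804367	12804389	AT	11
m077	chr12	12535924	12535948	CA	12
m078	chr13	12740200	12740213	A	13
m079	chr14	12727561	12727575	T	14
m080	chr15	13153878	13153908	AC	15
m081	chr16	12752561	12752593	AG	16
m082	chr17	12724982	12725016	AT	17
m083	chr18	12991121	12991157	CA	18
m084	chr19	13472716	13472735	A	19
m085	chr20	12597880	12597900	T	20
m086	chr21	12994148	12994190	AC	21
m087	chr22	12768088	12768132	AG	22
m088	chr1	16707806	16707852	AT	23
m089	chr2	16755396	16755444	CA	24
m090	chr3	16279969	16279979	A	10
m091	chr4	16816184	16816195	T	11
m092	chr5	16262390	16262414	AC	12
m093	chr6	16700387	16700413	AG	13
m094	chr7	16070359	16070387	AT	14
m095	chr8	16763045	16763075	CA	15
m096	chr9	16724251	16724267	A	16
m097	chr10	16166398	16166415	T	17
m098	chr11	16480328	16480364	AC	18
m099	chr12	16779676	16779714	AG	19
m100	chr13	16384570	16384610	AT	20
m101	chr14	16603272	16603314	CA	21
m102	chr15	16649936	16649958	A	22
m103	chr16	16360434	16360457	T	23
m104	chr17	16049283	16049331	AC	24
m105	chr18	16159385	16159405	AG	10
m106	chr19	16027172	16027194	AT	11
m107	chr20	16272873	16272897	CA	12
m108	chr21	16165116	16165129	A	13
m109	chr22	16623859	16623873	T	14
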