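table	exposure	outcome	method	n_snps	beta	se	pval	or	ci_low	ci_high	steiger_direction	steiger_p	q	q_df	q_pval
1	Family.unknownfamily.id.1000001214	Lumbar spine	Wald ratio	1	2.32E-01	8.95E-02	0.009	1.261	1.058	1.503	TRUE	1.89E-05	NA	NA	NA
1	Genus.Ruminococcustorquesgroup.id.14377	Lumbar spine	Wald ratio	1	3.90E-01	1.44E-01	0.006	1.476	1.112	1.959	TRUE	8.82E-04	NA	NA	NA
1	Genus.Tyzzerella3.id.11335	Lumbar spine	Wald ratio	1	2.80E-01	7.81E-02	0.0003	1.323	1.135	1.542	TRUE	6.55E-06	NA	NA	NA
1	Order.Gastranaerophilales.id.1591	Lumbar spine	Wald ratio	1	2.32E-01	8.95E-02	0.009	1.261	1.058	1.503	TRUE	1.89E-05	NA	NA	NA
1	Genus.Ruminococcustorquesgroup.id.14377	Forearm	Wald ratio	1	5.92E-01	2.58E-01	0.021	1.808	1.09	2.999	TRUE	9.45E-02	NA	NA	NA
1	Genus.Tyzzerella3.id.11335	Forearm	Wald ratio	1	2.60E-01	1.30E-01	0.044	1.297	1.005	1.672	TRUE	1.45E-04	NA	NA	NA
1	Genus.Tyzzerella3.id.11335	Femoral neck	Wald ratio	1	1.98E-01	6.76E-02	0.003	1.219	1.067	1.391	TRUE	1.67E-06	NA	NA	NA
1	Class.Actinobacteria.id.419	Heel	Wald ratio	1	-4.88E-02	1.95E-02	0.012	0.952	0.916	0.989	TRUE	9.45E-18	NA	NA	NA
1	Family.Bifidobacteriaceae.id.433	Heel	Wald ratio	1	-4.65E-02	1.86E-02	0.012	0.954	0.92	0.99	TRUE	7.06E-18	NA	NA	NA
1	Family.Oxalobacteraceae.id.2966	Heel	Wald ratio	1	5.02E-02	1.76E-02	0.004	1.051	1.015	1.088	TRUE	3.22E-07	NA	NA	NA
1	Genus.Ruminococcustorquesgroup.id.14377	Heel	Wald ratio	1	8.32E-02	3.06E-02	0.006	1.086	1.023	1.153	TRUE	7.60E-07	NA	NA	NA
1	Genus.Allisonella.id.2174	Heel	Wald ratio	1	2.71E-02	1.25E-02	0.03	1.027	1.002	1.052	TRUE	4.47E-08	NA	NA	NA
1	Genus.Bilophila.id.3170	Heel	Wald ratio	1	-4.54E-02	1.82E-02	0.012	0.955	0.922	0.99	TRUE	1.66E-18	NA	NA	NA
1	Order.Bifidobacteriales.id.432	Heel	Wald ratio	1	-4.65E-02	1.86E-02	0.012	0.954	0.92	0.99	TRUE	7.06E-18	NA	NA	NA
2	Class.Lentisphaeria.id.2250	Femoral neck	IVW	5	7.08E-02	3.43E-02	0.038	1.073	1.003	1.147	TRUE	2.04E-21	1.926	4	0.749
2	Family.Acidaminococcaceae.id.2166	Femoral neck	IVW	4	-1.37E-01	6.17E-02	0.025	0.871	0.772	0.983	TRUE	3.73E-14	2.609	3	0.455
2	Family.Prevotellaceae.id.960	Femoral neck	IVW	9	1.24E-01	4.14E-02	0.002	1.131	1.043	1.227	TRUE	6.06E-38	3.821	8	0.872
2	Genus.Ruminococcusgauvreauiigroup.id.11342	Femoral neck	IVW	7	-1.61E-01	5.01E-02	0.001	0.851	0.771	0.939	TRUE	1.20E-20	6.493	6	0.37
2	Genus.Actinomyces.id.423	Femoral neck	Wald ratio	1	1.94E-01	9.45E-02	0.039	1.214	1.008	1.461	TRUE	2.56E-04	NA	NA	NA
2	Genus.CandidatusSoleaferrea.id.11350	Femoral neck	IVW	3	-1.20E-01	5.16E-02	0.019	0.886	0.801	0.98	TRUE	5.56E-12	0.554	2	0.757
2	Genus.Coprococcus3.id.11303	Femoral neck	IVW	4	-1.95E-01	7.34E-02	0.007	0.822	0.712	0.949	TRUE	4.95E-12	0.9	3	0.825
2	Genus.Hungatella.id.11306	Femoral neck	IVW	2	-1.13E-01	5.18E-02	0.028	0.892	0.806	0.988	TRUE	9.26E-09	0.419	1	0.517
2	Genus.Turicibacter.id.2162	Femoral neck	IVW	6	-9.36E-02	4.27E-02	0.028	0.91	0.837	0.99	TRUE	7.52E-23	4.988	5	0.417
2	Order.Victivallales.id.2254	Femoral neck	IVW	5	7.08E-02	3.43E-02	0.038	1.073	1.003	1.147	TRUE	2.04E-21	1.926	4	0.749
2	Phylum.Lentisphaerae.id.2238	Femoral neck	IVW	4	8.12E-02	3.78E-02	0.031	1.084	1.007	1.168	TRUE	1.18E-17	1.479	3	0.686
3	Genus.unknowngenus.id.2071	Forearm	IVW	9	1.77E-01	8.52E-02	0.038	1.193	1.009	1.41	TRUE	4.78E-16	3.888	8	0.867
3	Genus.Sellimonas.id.14369	Forearm	IVW	6	1.19E-01	5.33E-02	0.025	1.126	1.014	1.251	TRUE	3.36E-19	5.019	5	0.413
3	Genus.Oscillospira.id.2064	Forearm	IVW	12	1.42E-01	6.59E-02	0.031	1.152	1.012	1.311	TRUE	7.64E-26	6.675	11	0.824
3	Genus.Olsenella.id.822	Forearm	IVW	7	-1.34E-01	6.71E-02	0.046	0.874	0.767	0.997	TRUE	1.78E-19	8.635	6	0.195
3	Genus.LachnospiraceaeND3007group.id.11317	Forearm	Wald ratio	1	-7.74E-01	3.39E-01	0.022	0.461	0.237	0.896	TRUE	1.69E-01	NA	NA	NA
3	Genus.Escherichia.Shigella.id.3504	Forearm	IVW	4	-2.95E-01	1.23E-01	0.016	0.744	0.585	0.946	TRUE	8.58E-07	0.495	3	0.919
3	Genus.Butyrivibrio.id.1993	Forearm	IVW	7	-1.27E-01	6.42E-02	0.048	0.88	0.776	0.999	TRUE	1.08E-20	9.564	6	0.144
3	Genus.Alistipes.id.968	Forearm	IVW	9	-2.58E-01	9.36E-02	0.005	0.772	0.642	0.927	TRUE	8.34E-07	3.414	8	0.905
3	Genus.Ruminococcusgnavusgroup.id.14376	Forearm	IVW	7	-2.08E-01	8.61E-02	0.015	0.812	0.686	0.961	TRUE	2.78E-14	9.789	6	0.133
3	Family.Rikenellaceae.id.967	Forearm	IVW	10	-2.71E-01	8.84E-02	0.002	0.762	0.641	0.907	TRUE	7.84E-13	5.79	9	0.76
3	Family.Prevotellaceae.id.960	Forearm	IVW	9	1.98E-01	9.09E-02	0.029	1.219	1.02	1.457	TRUE	4.78E-16	8.878	8	0.352
4	Order.Coriobacteriales.id.810	Lumbar spine	IVW	5	1.68E-01	7.88E-02	0.033	1.182	1.013	1.38	TRUE	2.73E-14	2.005	4	0.7349
4	Genus.Terrisporobacter.id.11348	Lumbar spine	IVW	2	-1.52E-01	6.69E-02	0.023	0.859	0.753	0.979	TRUE	5.81E-09	NA	NA	NA
4	Genus.RuminococcaceaeUCG005.id.11363	Lumbar spine	IVW	9	1.44E-01	6.74E-02	0.032	1.155	1.012	1.318	TRUE	8.92E-35	14.26	8	0.0751
4	Genus.RuminococcaceaeUCG003.id.11361	Lumbar spine	IVW	9	-1.08E-01	5.22E-02	0.038	0.897	0.81	0.994	TRUE	3.47E-31	8.596	8	0.3775
4	Genus.Prevotella9.id.11183	Lumbar spine	IVW	6	1.83E-01	5.12E-02	0.0003	1.2	1.086	1.327	TRUE	2.51E-21	3.621	5	0.6051
4	Genus.LachnospiraceaeNK4A136group.id.11319	Lumbar spine	IVW	8	1.12E-01	4.68E-02	0.017	1.118	1.02	1.225	TRUE	3.67E-37	4.978	7	0.6627
4	Genus.FamilyXIIIUCG001.id.11294	Lumbar spine	IVW	5	-1.26E-01	6.05E-02	0.037	0.881	0.783	0.992	TRUE	6.52E-19	0.494	4	0.9741
4	Genus.FamilyXIIIAD3011group.id.11293	Lumbar spine	IVW	7	1.17E-01	5.62E-02	0.037	1.123	1.006	1.254	TRUE	8.18E-24	2.847	6	0.8278
4	Genus.Escherichia.Shigella.id.3504	Lumbar spine	IVW	3	-2.01E-01	8.33E-02	0.015	0.817	0.694	0.962	TRUE	1.52E-09	1.227	2	0.5414
4	Genus.Alistipes.id.968	Lumbar spine	IVW	5	-1.61E-01	8.18E-02	0.048	0.851	0.725	0.999	TRUE	1.89E-13	4.272	4	0.3704
4	Genus.Actinomyces.id.423	Lumbar spine	Wald ratio	1	2.31E-01	1.10E-01	0.035	1.259	1.015	1.562	TRUE	3.60E-04	NA	NA	NA
4	Family.Coriobacteriaceae.id.811	Lumbar spine	IVW	5	1.68E-01	7.88E-02	0.033	1.182	1.013	1.38	TRUE	2.73E-14	0.285	1	0.5934
4	Family.Clostridiaceae1.id.1869	Lumbar spine	IVW	2	-1.86E-01	9.31E-02	0.045	0.83	0.691	0.996	TRUE	5.11E-08	0.285	1	0.5934
4	Class.Coriobacteriia.id.809	Lumbar spine	IVW	5	1.68E-01	7.88E-02	0.033	1.182	1.013	1.38	TRUE	2.73E-14	2.005	4	0.7349
5	Family.Actinomycetaceae.id.421	Heel	IVW	2	4.49E-02	1.89E-02	0.017	1.045	1.007	1.085	TRUE	1.75E-11	1.725	1	0.1891
5	Family.FamilyXI.id.1936	Heel	IVW	7	-1.49E-02	5.84E-03	0.01	0.985	0.974	0.996	TRUE	1.12E-35	3.932	6	0.6859
5	Family.unknownfamily.id.1000006161	Heel	IVW	10	1.62E-02	6.11E-03	0.008	1.016	1.004	1.028	TRUE	1.02E-50	7.102	9	0.6265
5	Genus.Eubacteriumcoprostanoligenesgroup.id.11375	Heel	IVW	7	6.41E-02	1.76E-02	0.0002	1.066	1.029	1.103	TRUE	8.98E-31	10.72	6	0.0974
5	Genus.Eisenbergiella.id.11304	Heel	IVW	5	-3.67E-02	9.48E-03	0.0001	0.963	0.946	0.982	TRUE	2.13E-23	2.603	4	0.6263
5	Genus.RikenellaceaeRC9gutgroup.id.11191	Heel	IVW	6	-0.0113267	0.0084897	0.182	0.988	0.972	1.005	TRUE	5.98E-30	8.417	5	0.1347
5	Genus.RuminococcaceaeNK4A214group.id.11358	Heel	IVW	7	-3.16E-02	1.24E-02	0.011	0.968	0.945	0.992	FALSE	6.82E-01	2.221	6	0.8983
5	Genus.Turicibacter.id.2162.summary	Heel	IVW	3	-8.88E-02	1.51E-02	4.5E-09	0.915	0.888	0.942	FALSE	4.17E-01	1.032	2	0.5969
5	Genus.unknowngenus.id.1000006162	Heel	IVW	9	1.86E-02	6.42E-03	0.003	1.018	1.005	1.031	TRUE	8.19E-46	5.682	8	0.6828
5	Order.Actinomycetales.id.420	Heel	IVW	2	4.50E-02	1.89E-02	0.017	1.046	1.007	1.085	TRUE	1.92E-11	1.714	1	0.1905
5	Order.NB1n.id.3953	Heel	IVW	10	1.62E-02	6.11E-03	0.008	1.016	1.004	1.028	TRUE	1.02E-50	7.102	9	0.6265
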