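gene	B cells	CD4 T cells	CD8 T cells	NK cells	Monocytes	Macrophages	Dendritic cells	Neutrophils	Eosinophils	Mast cells
Adgre1	6.439	4.857	3.611	7.603	1.571	418.394	4.991	4.555	6.432	5.990
Alox15	3.208	1.611	6.111	7.802	7.652	6.441	0.857	1.921	297.618	0.560
Batf3	5.811	3.162	0.806	1.648	2.303	0.670	251.231	5.198	1.209	1.650
C1qa	7.433	5.552	1.773	2.367	0.524	481.724	3.553	2.271	5.540	7.221
C1qb	7.733	2.731	2.369	4.519	3.798	305.430	7.139	1.149	6.426	2.524
Ccr2	2.707	5.652	5.462	1.034	572.192	1.432	4.969	3.747	7.949	5.062
Ccr3	3.408	5.825	6.551	7.490	3.305	7.790	6.996	7.768	507.431	1.805
Ccr7	5.650	575.053	3.601	7.258	6.347	5.098	5.101	7.783	2.339	1.419
Cd14	1.212	2.487	2.004	4.174	333.120	3.538	7.384	0.570	4.267	5.677
Cd19	493.119	6.781	7.868	5.335	6.408	7.001	4.667	5.245	1.871	3.197
Cd28	6.941	294.274	4.333	7.265	5.643	2.587	7.950	6.168	4.687	6.050
Cd36	3.297	0.636	7.197	5.856	259.936	7.259	1.259	5.120	4.029	0.931
Cd3d	3.120	531.364	0.567	4.188	2.171	0.532	5.448	5.668	5.480	2.298
Cd3e	4.485	282.683	2.848	6.179	5.589	7.788	7.105	3.343	7.266	5.108
Cd3g	1.573	3.590	331.662	0.797	6.221	1.598	6.055	6.056	4.127	7.894
Cd4	0.526	490.220	2.906	1.536	3.931	5.822	4.776	1.677	4.804	2.484
Cd68	1.513	4.615	3.330	4.016	0.923	492.215	5.803	0.501	4.399	2.018
Cd79a	294.045	5.800	1.007	2.753	2.486	5.408	3.004	7.004	6.753	0.821
Cd79b	510.735	6.321	3.920	2.239	6.062	4.617	1.367	3.078	6.466	3.330
Cd83	6.860	3.320	3.447	4.273	1.482	1.790	352.815	7.439	5.329	3.986
Cd8a	5.457	0.905	271.687	3.143	1.603	3.798	4.430	2.058	7.703	2.520
Cd8b1	1.266	5.749	542.828	7.786	6.372	6.579	2.778	0.586	6.290	6.476
Clec9a	7.811	2.381	2.041	4.700	7.287	2.594	441.589	4.005	4.729	3.077
Cpa3	7.767	0.585	7.804	7.376	3.663	2.700	2.783	6.257	1.060	424.200
Cr2	579.608	3.672	5.241	0.517	6.065	5.000	7.769	1.179	4.336	4.907
Csf1r	0.641	6.669	7.620	0.906	7.439	458.747	5.156	6.027	6.256	4.010
Csf3r	3.092	3.000	3.415	7.065	3.864	7.024	0.774	298.863	2.906	4.468
Cxcr2	3.213	7.070	7.574	7.879	4.073	1.792	4.725	325.733	2.880	2.609
Ebf1	589.862	1.177	7.737	7.573	1.399	2.771	5.868	5.389	2.948	6.150
Elane	6.729	3.579	1.820	6.859	2.722	5.124	7.986	580.212	6.789	4.592
Eomes	5.644	4.716	264.068	6.890	3.608	3.075	7.553	0.717	4.919	0.897
Epx	2.758	1.549	7.932	4.957	4.122	3.833	5.825	1.260	492.405	0.815
Fcer1a	1.580	5.300	1.583	7.318	5.817	1.998	2.302	4.990	7.899	442.750
Fcer2a	327.621	2.919	7.093	7.356	7.633	4.316	1.893	1.636	7.361	1.700
Fcn1	2.535	7.759	3.538	7.631	396.393	4.412	1.522	5.178	1.857	5.089
Flt3	1.813	1.795	7.778	6.279	3.331	6.596	317.592	3.905	5.355	2.527
Fpr1	7.707	5.419	0.692	0.725	457.342	2.165	3.688	4.513	0.877	5.536
Gata2	3.165	2.684	7.504	0.911	5.852	2.688	3.726	0.831	1.832	315.278
Gzma	2.459	4.203	5.433	323.836	4.781	2.387	4.757	7.538	7.651	7.372
Gzmk	2.608	3.643	580.255	3.729	2.645	0.772	7.475	6.410	4.751	5.015
Gzmm	2.488	2.293	302.287	6.521	5.488	5.529	2.799	1.987	7.414	2.040
Hdc	6.899	2.821	3.942	6.942	5.746	4.083	4.414	3.820	7.871	561.132
Il5ra	2.981	2.800	0.954	3.069	5.972	5.561	4.354	1.896	453.972	1.376
Il7r	5.157	285.131	4.749	3.773	1.243	2.043	6.792	2.462	7.763	6.623
Irf8	7.758	3.537	3.201	5.884	7.282	4.693	295.853	4.893	0.774	5.793
Itgax	1.754	2.018	3.222	4.094	2.201	3.268	575.826	3.810	1.650	5.253
Kit	3.141	7.895	5.443	3.316	6.866	2.686	4.390	1.684	7.981	403.268
Klrb1c	6.881	3.864	2.746	515.741	2.714	2.120	2.859	7.900	0.886	2.650
Klrd1	4.679	5.688	4.084	373.612	7.695	7.949	3.820	2.652	1.237	4.616
Klrg1	4.252	2.854	366.515	0.570	4.436	3.658	6.630	3.752	0.698	6.103
Klrk1	2.823	3.401	4.869	480.643	4.013	0.803	6.955	3.827	7.127	7.128
Lck	7.665	2.468	557.168	2.921	3.901	7.714	1.643	4.915	3.231	5.479
Lef1	3.694	528.699	3.804	5.517	0.646	2.214	0.560	1.894	5.276	0.681
Ltf	3.756	4.379	3.730	1.037	3.224	1.617	2.758	434.641	5.975	1.042
Mcpt4	4.360	2.592	2.407	2.361	3.983	0.760	3.859	3.711	6.466	412.993
Mertk	3.354	4.773	0.839	2.223	7.555	442.672	2.022	2.354	0.971	4.371
Mmp8	5.959	4.953	3.451	3.375	6.754	2.012	1.481	391.433	7.036	1.807
Mpo	5.851	4.100	0.896	2.255	5.739	6.537	1.141	332.772	2.525	0.777
Mrc1	4.309	7.803	5.338	3.695	1.418	522.572	4.460	6.193	5.895	5.977
Ms4a1	480.299	6.370	6.833	7.361	4.988	7.997	2.270	7.415	7.754	1.308
Ms4a2	3.983	6.618	3.632	6.866	3.787	0.840	5.386	3.959	7.158	285.459
Ncr1	6.403	7.324	6.498	420.098	2.872	2.625	5.901	5.458	2.375	3.126
Nkg7	7.646	1.650	6.120	436.697	1.520	4.855	5.924	4.287	5.837	1.114
Pax5	382.915	7.603	6.365	2.233	6.004	1.829	2.945	7.916	6.884	5.238
Prf1	6.829	6.016	4.164	491.574	0.709	5.220	2.811	4.279	5.941	7.497
Prg2	6.140	1.639	2.198	4.173	7.737	6.374	3.200	7.532	542.086	3.777
Ptgdr2	3.662	0.687	2.675	5.465	1.932	2.489	1.313	6.106	534.661	4.140
Rnase2a	6.692	2.831	2.384	3.222	3.351	4.672	1.167	6.521	317.103	6.892
S100a12	1.000	2.008	7.519	5.319	408.555	6.511	2.832	2.128	4.289	4.528
S100a8	1.821	0.793	3.086	7.561	3.176	4.580	0.686	582.449	6.697	1.705
S100a9	4.818	2.119	6.063	2.821	2.308	7.996	1.158	476.464	1.766	7.805
Siglec8	4.919	0.965	3.647	1.104	5.438	4.091	3.030	2.809	592.693	1.880
Sirpa	0.516	1.842	5.776	2.162	331.632	7.562	3.203	7.571	5.861	5.325
Tcf7	6.185	505.793	6.377	6.823	4.081	0.915	3.323	4.960	1.696	2.695
Tpsab1	1.309	4.255	1.125	4.187	6.040	5.964	4.111	1.093	4.061	431.175
Trem2	6.022	4.548	3.306	5.788	3.587	254.523	1.415	0.946	3.467	6.725
Vcan	2.152	6.745	1.374	3.135	341.029	1.144	4.016	3.284	5.362	4.968
Xcl1	6.659	1.539	2.671	262.739	5.126	6.143	2.552	6.292	4.454	3.119
Xcr1	1.061	5.069	3.191	6.808	1.722	6.714	435.746	7.642	6.866	7.531
Zbtb46	2.529	4.883	6.813	7.350	4.238	5.608	335.674	2.701	3.583	0.950
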