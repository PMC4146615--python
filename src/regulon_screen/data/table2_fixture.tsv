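gene	fc_a	q_a	fc_b	q_b	function
SCO0319	84	2e-28	>100	9e-12	Hypothetical protein
SCO0320	79	3e-21	52	5e-10	Quinone oxidoreductase
SCO1178	52	2e-21	49	1e-9	NAD-dependent epimerase/dehydratase
SCO4266	30	2e-28	14	4e-7	Oxidoreductase
SCO7688	28	8e-2	1	1e0	Hypothetical protein
SCO1177	23	7e-18	32	2e-7	GntR-family transcriptional regulator
SCO0321	18	7e-18	26	9e-8	Carboxylesterase
SCO1909	18	1e-22	11	7e-6	Monooxygenase
SCO1734	15	4e-11	24	2e-5	Secreted cellulose binding protein
SCO4021	11	6e-2	2	8e-1	Two-component histidine kinase
SCO2478	7	3e-1	>100	1e-3	Flavoprotein reductase
SCO7682	6	4e-1	<1	8e-1	Non-ribosomal peptide synthase
SCO4157	6	4e-1	4	4e-1	Protease
SCO4020	6	3e-3	2	8e-1	Two-component response regulator
SCO6165	6	3e-1	>100	8e-4	Hypothetical protein
SCO1697	5	8e-3	1	1e0	SoxR
SCO2878	5	4e-1	<1	5e-1	Hypothetical protein
SCO7008	5	3e-9	37	2e-9	ABC transporter
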