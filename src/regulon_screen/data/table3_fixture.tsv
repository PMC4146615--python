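gene	fold_soxr	fold_act	group	function
SCO0319	4	24	candidate	Hypothetical protein
SCO0320	86	34	candidate	Quinone oxidoreductase
SCO0321	59	61	candidate	Carboxylesterase
SCO1177	9	11	candidate	GntR-family transcriptional regulator
SCO1734	8	3	candidate	Secreted cellulose binding protein
SCO4020	1	1	candidate	Two-component response regulator
SCO4021	10	2	candidate	Two-component histidine kinase
SCO4157	1	2	candidate	Protease
SCO6165	1	<1	candidate	Hypothetical protein
SCO1697	47	1	regulator	SoxR
SCO1178	60	29	known	NAD-dependent epimerase/dehydratase
SCO1909	30	30	known	Monooxygenase
SCO2478	31	15	known	Flavoprotein reductase
SCO4266	29	59	known	Oxidoreductase
SCO7008	15	30	known	ABC transporter
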