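variant	gene	stratum	cases_determined	case_carriers	controls_determined	control_carriers
rs572750141	SHARPIN	cohort1	2383	10	13973	7
rs572750141	SHARPIN	cohort2	2180	1	2486	1
rs531355933	TYK2	cohort1	2379	4	13973	5
rs531355933	TYK2	cohort2	2180	3	2486	4
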