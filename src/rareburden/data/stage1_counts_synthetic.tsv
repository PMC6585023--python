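variant	gene	position	case_carriers	cases_determined	control_carriers	controls_determined
rs980452538	PXN	12:120651694	0	2176	0	909
rs572750141	SHARPIN	8:145154709	9	2172	0	916
rs774802799	SHARPIN	8:145154228	0	2183	0	917
rs531355933	TYK2	19:10477232	3	2181	0	916
rs771874615	ZNF786	7:148769094	0	2179	0	914
rs762922242	ZNF786	7:148767975	0	2180	0	915
NA_ZNF786_G656D	ZNF786	7:148767897	0	2175	0	914
synthetic_01	PXN	12:120000001	1	1102	2	592
synthetic_02	PXN	12:120000002	0	1102	1	592
synthetic_03	SHARPIN	8:145000001	2	1102	3	592
synthetic_04	SHARPIN	8:145000002	0	1102	1	592
synthetic_05	TYK2	19:10000001	1	1102	1	592
synthetic_06	TYK2	19:10000002	0	1102	2	592
synthetic_07	ZNF786	7:148000001	1	1102	1	592
synthetic_08	ZNF786	7:148000002	0	1102	4	592
synthetic_09	ZNF786	7:148000003	2	1102	1	592
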