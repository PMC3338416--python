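substituent_id	smiles	family
SUB01	C	alkyl
SUB02	CC	alkyl
SUB03	CCC	alkyl
SUB04	CCCC	alkyl
SUB05	C(C)C	alkyl
SUB06	C(C)(C)C	alkyl
SUB07	C=C	alkyl
SUB08	C#C	alkyl
SUB09	F	inert
SUB10	Cl	inert
SUB11	Br	inert
SUB12	I	inert
SUB13	C(F)(F)F	inert
SUB14	S	inert
SUB15	SC	inert
SUB16	OC	ether
SUB17	OCC	ether
SUB18	OC(F)(F)F	ether
SUB19	Oc8ccccc8	ether
SUB20	O	hydroxy
SUB21	CO	hydroxy
SUB22	CCO	hydroxy
SUB23	N	amine
SUB24	NC	amine
SUB25	N(C)C	amine
SUB26	CN	amine
SUB27	CCN	amine
SUB28	N8CCCC8	amine
SUB29	CN8CCOCC8	amine
SUB30	C(=O)O	carbonyl
SUB31	C(=O)OC	carbonyl
SUB32	C(=O)C	carbonyl
SUB33	C(=O)N	carbonyl
SUB34	C(=O)NC	carbonyl
SUB35	C#N	polar
SUB36	[N+](=O)[O-]	polar
SUB37	S(=O)(=O)C	polar
SUB38	S(=O)(=O)N	polar
SUB39	c8ccccc8	aryl
SUB40	Cc8ccccc8	aryl
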