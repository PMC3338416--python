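scaffold_id	template
SCF01	c1ccc({R})cc1
SCF02	c1ccc2cc({R})ccc2c1
SCF03	c1ccnc({R})c1
SCF04	c1ccc(-c2ccc({R})cc2)cc1
SCF05	c1ccc2c(c1)cc({R})[nH]2
SCF06	c1ccc2c(c1)nc({R})o2
SCF07	c1ccc2c(c1)nc({R})s2
SCF08	c1ccc2c(c1)ncc({R})n2
SCF09	c1cnc({R})nc1
SCF10	c1cc({R})on1
SCF11	c1cc({R})cs1
SCF12	c1cc({R})co1
SCF13	c1cc({R})[nH]n1
SCF14	C1CCC({R})CC1
SCF15	C1CCN({R})CC1
SCF16	C1CCOC({R})C1
SCF17	c1ccc(N({R})C2CC2)cc1
SCF18	c1ccc(C(=O)N({R})C)cc1
SCF19	c1ccc(S(=O)(=O)N({R})C)cc1
SCF20	c1ccc(-n2cnc({R})c2)cc1
SCF21	c1ccc(-c2nnc({R})o2)cc1
SCF22	c1ccc(-c2csc({R})n2)cc1
SCF23	c1ccc2[nH]c({R})nc2c1
SCF24	c1ccc2c(c1)c({R})cn2C
SCF25	c1cc2ccc({R})cc2cn1
SCF26	C1CN({R})CCN1C
SCF27	c1ccc(CN({R})C2CCCC2)cc1
SCF28	c1ccc(-c2ccnc({R})n2)cc1
SCF29	c1ccc2c(c1)ccc1cc({R})ccc12
SCF30	c1ccc(OCC({R})=O)cc1
SCF31	c1ccc(-c2cc({R})no2)cc1
SCF32	C1COc2ccc({R})cc2O1
SCF33	c1ccc(-c2ncc({R})s2)cc1
SCF34	c1cnc2[nH]cc({R})c2c1
SCF35	c1ccc(C2CC({R})=NN2)cc1
SCF36	c1ccc(-c2cnc({R})cn2)cc1
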