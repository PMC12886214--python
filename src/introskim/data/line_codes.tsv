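# Published introgression codes for the 68 WRC_Mut wheat x Ae. mutica lines.
# One row per line; codes comma-separated in printed order. A trailing '*' marks
# segments detected only by skim-sequencing (missed by KASP and GISH).
line_id	codes
WRC21_Mut2	2T.A2
WRC21_Mut3	2T.D3
WRC21_Mut4	7T.D5
WRC21_Mut5	2T.D10,6T.D3
WRC21_Mut6	2T.D12,3Tcf,5T.cf
WRC21_Mut7	1D.D1
WRC21_Mut10	2T.B1,4T.D4,4T.D10*,5T.D13
WRC21_Mut12	4T.D3
WRC21_Mut13	5T.D8,7T.A6
WRC21_Mut14	2T.D2
WRC21_Mut15	2T.D11,7T.A4
WRC21_Mut16	2T.D11
WRC21_Mut17	2T.D9
WRC21_Mut18	2T.D8
WRC21_Mut19	2T.D7
WRC21_Mut20	2T.D7
WRC21_Mut21	2T.A3,2T.D6,2T.D15
WRC21_Mut22	4T.D3
WRC21_Mut23	3T.D2
WRC21_Mut24	4T.D5,7T.D10*
WRC21_Mut25	4T.D6
WRC21_Mut26	4T.D3
WRC21_Mut27	3T.A1,5T.D5
WRC21_Mut28	3T.D2
WRC21_Mut29	2T.D12,5T.D7
WRC21_Mut30	3T.A1,5T.D5
WRC21_Mut31	1T.B1
WRC21_Mut32	1T.B1,6T.B2
WRC21_Mut33	6T.W1
WRC21_Mut34	5T.D11,6T.B1
WRC21_Mut35	3T.D3
WRC21_Mut36	3T.D3,5T.D6
WRC21_Mut37	5T.D6
WRC21_Mut38	6T.B1
WRC21_Mut39	4T.D7,4T.D9,5T.D5,7T.D7
WRC21_Mut40	2T.D1
WRC21_Mut41	3T.D4,7T.D4
WRC21_Mut42	3T.D2
WRC21_Mut43	3T.D2
WRC21_Mut44	3T.A1,5T.D5
WRC21_Mut45	3T.A1,5T.D5
WRC21_Mut46	3T.D1
WRC21_Mut47	2T.D5
WRC21_Mut48	4T.D1
WRC21_Mut49	3T.A1,5T.D3,5T.D10,7T.A7*
WRC21_Mut50	3T.B1,7T.D8
WRC21_Mut51	2T.D5
WRC21_Mut52	6T.A1
WRC21_Mut53	7T.D4
WRC21_Mut54	7T.A2
WRC21_Mut55	5T.D4
WRC21_Mut56	5T.D5
WRC21_Mut57	7T.A5
WRC23_Mut58	5T.D5
WRC23_Mut62	2T.D4
WRC23_Mut66	4T.D3
WRC23_Mut70	1T.A2
WRC23_Mut73	1T.B1,4T.D10
WRC23_Mut74	3T.D3
WRC23_Mut75	4T.D7,5T.D5,7T.D6
WRC23_Mut77	4T.D8*,5T.D5,7T.D9
WRC23_Mut78	2T.D12,5T.D7
WRC23_Mut79	2T.D13,7T.D8add
WRC23_Mut80	3T.A2,7T.A3
WRC23_Mut82	3T.A1,5T.D9
WRC23_Mut84	2T.D8
WRC23_Mut85	2T.D14,6T.D3
WRC24_Mut86	6T.B3*
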