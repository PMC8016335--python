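# provenance: source Table 5 - per-specimen fingerprint identifications of the sampled bone points ('-' = no result; one KwaGandaganda specimen, KWG4, is absent from the printed table)
site	accession	date	period	zooms_code	id	observations
Collingham	N5 BS1	1770–1880 BP	Pre-contact	CHS1	-	
Collingham	T5 VP1	Undated		CHS2	-	Bone was heated
Collingham	P5 BSD	1770–1880 BP	Pre-contact	CHS3	Alcelaphini	Bone is coated in poison
Collingham	S4 BSV2	1770–1880 BP	Pre-contact	CHS4	-	
Collingham	P4 BSVG	1770–1880 BP	Pre-contact	CHS5	-	
Collingham	R4 BSV6	1770–1880 BP	Pre-contact	CHS6	Reduncini	
Collingham	S4 FGBS	1770–1880 BP	Pre-contact	CHS7	-	Bone was heated
Collingham	P5 GAD	1770–1880 BP	Pre-contact	CHS8	Aonyx	
Driel	D3 Surf	<1775±40 BP	Pre-contact	DR1	-	
Driel	D3 (4)	>1775±40 BP	Pre-contact	DR2	-	
Driel	F3 (2)	<1775±40 BP	Pre-contact	DR3	Tragelaphini	
Driel	unlabelled			DR4	-	Bone was heated
Driel	E3 (3)	1775±40 BP	Pre-contact	DR5	-	
Driel	E3 (3) (2)	1775±40 BP	Pre-contact	DR6	-	
Driel	E4 Surf	<1775±40 BP	Pre-contact	DR7	Tragelaphini	
Driel	E3 (2)	<1775±40 BP	Pre-contact	DR8	-	
Good Hope	C4 (2)	<2160±40 BP	Pre-contact	GH1	Leporidae	Bone is polished and discoloured
Good Hope	B4 (5)	<7670±55 BP	Pre-contact	GH2	-	Small mammal limb shaft
Good Hope	C4 (3)	2160±40 BP	Pre-contact	GH3	-	
Good Hope	B4 (4)	>2160±40 BP	Pre-contact	GH4	-	Bone is calcined
Good Hope	B4 (1)	<2160±40 BP	Pre-contact	GH5	-	
Good Hope	B5 (2)	<2160±40 BP	Pre-contact	GH6	Tragelaphini	Base is deliberately squared
Good Hope	B3 (6)	>7670±55 BP	Pre-contact	GH7	-	Small mammal limb shaft
Good Hope	B4 (3)	2160±40 BP	Pre-contact	GH8	-	
Good Hope	C5 SFC (3)	2160±40 BP	Pre-contact	GH9	Leporidae	
Good Hope	C3 (2)	<2160±40 BP	Pre-contact	GH10	Alcelaphini	
KwaGandaganda	25c (3)	1395±60 BP	Contact	KWG1	Syncerus	Robust, peg-like piece
KwaGandaganda	T2U5 (3)	<1080±60 BP	Contact	KWG2	Alcelaphini	
KwaGandaganda	Sq25 Ext (55–70)	1395±60 BP	Contact	KWG3	Alcelaphini	
KwaGandaganda	F6 (2)			KWG5	Giraffa	
KwaGandaganda	SVP 69	<1080±60 BP	Contact	KWG6	Tragelaphini	
KwaGandaganda	25a Sq3 (2)	1395±60 BP	Contact	KWG7	-	
KwaGandaganda	Sq3 (2)			KWG8	Equus	
KwaGandaganda	G2 Pit 1 (55–80)			KWG9	-	Bone was heated
KwaGandaganda	Sq25 E10	1395±60 BP	Contact	KWG10	Tragelaphini	
KwaGandaganda	DB30 (1)	>1395±60 BP	Contact	KWG11		Bone discoloured, possibly from heat
Maqonqo	H7 MBS9(G)	>6300 BP	Pre-contact	MQ1	Equus	
Maqonqo	L7 MBS7	6300 BP	Pre-contact	MQ2	-	Bone was heated
Maqonqo	J7 MBS8	<6300 BP	Pre-contact	MQ3	-	
Maqonqo	L7 CBS5	7460 BP	Pre-contact	MQ4	-	
Maqonqo	L8 DBS3	8670 BP	Pre-contact	MQ5	-	
Maqonqo	K6 MBS9	>6300 BP	Pre-contact	MQ6	Reduncini	
Maqonqo	L7 MBS3	4960 BP	Pre-contact	MQ7	-	
Maqonqo	J7 BS1	3560 BP	Pre-contact	MQ8	-	
Maqonqo	L7 MBS2	4140 BP	Pre-contact	MQ9	-	
Maqonqo	L7 MBS6	>5680 BP	Pre-contact	MQ10	-	
Maqonqo	L7 CBS1	<7460 BP	Pre-contact	MQ11	-	Bone was heated
Maqonqo	K7 MBS4	5680 BP	Pre-contact	MQ12	-	Bone has incised decoration
Mgede	J4 CBS2	>820±50 BP	Contact	MG1	Tragelaphini	
Mgede	J3 CBS1	820±50 BP	Contact	MG2	Alcelaphini	
Mgede	J4 SC1	>820±50 BP	Contact	MG3	Alcelaphini	
Mgede	J4 CBS1	820±50 BP	Contact	MG4	Reduncini	
Mhlwazini	F4 USOBS	2760±50 BP	Pre-contact	MWZ1	-	
Mhlwazini	D5 BS2	190±45 BP	Contact	MWZ2	-	
Mzinyashana	F3 FAP	970±50 BP	Contact	MZ1	-	Circumferential incised decoration
Mzinyashana	F5 LBS1	2630±60 BP	Pre-contact	MZ2	Hippotragini	Bone is polished
Mzinyashana	F4 DBS5	1520±20 BP	Contact	MZ3	Tragelaphini	Bone is polished
Mzinyashana	F4 DBS5 (2)	1520±20 BP	Contact	MZ4	Tragelaphini	
Mzinyashana	G4 LBS1	2630±60 BP	Pre-contact	MZ5	Alcelaphini	
Mzinyashana	F4 LBS6	2260±50 BP	Pre-contact	MZ6	Alcelaphini	
Mzinyashana	F5 LBS6	2260±50 BP	Pre-contact	MZ7	Alcelaphini	Bone is polished
Mzinyashana	F4 LBS1	2630±60 BP	Pre-contact	MZ8	Tragelaphini	
Ndondondwane	K10 SF-10	<1190±50 BP	Contact	NDW1	Syncerus	Base is deliberately squared
Ndondondwane	G12 (1)	1190±50 BP	Contact	NDW2	-	
Ndondondwane	H10 (2) 3038	1220±50 BP	Contact	NDW3	-	
Ndondondwane	E10 (1) 2877	1190±50 BP	Contact	NDW4	Alcelaphini	
Ndondondwane	H10 (1)	1190±50 BP	Contact	NDW5	Alcelaphini	
Ndondondwane	G11 (2)	1220±50 BP	Contact	NDW6	Reduncini	Base is deliberately squared
Ndondondwane	H10 (1) (2)	>1190±50 BP	Contact	NDW7	Alcelaphini	
Ndondondwane	NDO24 P1 west	>1190±50 BP	Contact	NDW8	Alcelaphini	
Ndondondwane	NDO26 R1 west	>1190±50 BP	Contact	NDW9	Alcelaphini	
Ndondondwane	NDO midden 1 L1	1190±50 BP	Contact	NDW10	Alcelaphini	
Ndondondwane	NDO82 1762	<1220±50 BP	Contact	NDW11	Alcelaphini	
Ndondondwane	NDO I7 (2) 3970	1220±50 BP	Contact	NDW12	Alcelaphini	Base is deliberately squared
Nkupe	S11 MBS1	3950±70 BP	Pre-contact	NK1	Tragelaphini	Bone is polished
Nkupe	S10 MBS1	3950±70 BP	Pre-contact	NK2	-	Distal half was heated
Nkupe	R10 WA3B	4590±70 BP	Pre-contact	NK3	-	
Nkupe	R13 LSBS	2480±60 BP	Pre-contact	NK4	Reduncini	
Nkupe	513 VP1	2480±60 BP	Pre-contact	NK5	-	Bone is polished and base squared
Nkupe	513 WA1C	3190±60 BP	Pre-contact	NK6	-	Bone was heated
Wosi	G3 T2 OC (2)	1290±50 BP	Contact	WZ1	Alcelaphini	
Wosi	G4 T1 O6	1290±50 BP	Contact	WZ2	Syncerus	
Wosi	G2 Q4 T4 OC	1290±50 BP	Contact	WZ3	Reduncini	
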