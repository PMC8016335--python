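# provenance: source Table 1 - faunal MNI counts per site (X = presence only, from NISP-only reports); BOV I-IV are unassigned bovid size classes
taxon	common_name	tribe_printed	tribe	Collingham	Driel	Good Hope	KwaGandaganda	Maqonqo	Mgede	Mhlwazini	Mzinyashana	Ndondondwane	Nkupe	Wosi
Homo sapiens	human				1			1	1		1		2	
Papio ursinus	chacma baboon			7		12		13	1	11	1		18	5
Chlorocebus aethiops	vervet monkey						X							4
Lupulella mesomelas	black-backed jackal			4	1			15	4	6	7		10	2
Lycaon pictus	wild dog							2			2		2	
Vulpes chama	cape fox				1			1						
Canis familiaris	dog						X					X		8
Crocuta crocuta	spotted hyaena										1			
Parahyaena brunnea	brown hyaena			1				2						
Caracal caracal	caracal			1	1			3	2	1	4		12	2
Felis lybica	wildcat			3	1		X	1	4		3		14	2
Leptailurus serval	serval													2
Genetta genetta	genet							2					7	1
Genetta tigrina	Cape genet						X							
Panthera leo	lion							3					2	
Panthera pardus	leopard			3			X	1	1				2	
Equus quagga	zebra					1	X	23	2		5		1	1
Procavia capensis	hyrax			29	6	11	X	36	7	11			53	
Proteles cristatus	aardwolf				2			3			2			
Phacochoerus sp.	warthog				4	1	X	39		1	10		4	4
Potamochoerus larvatus	bushpig			2			X	4	5		14		11	4
Orycteropus afer	aardvark			1	2			14	2		7		5	3
Smutsia temminckii	pangolin						X	4			1			
Mellivora capensis	honey badger							1	1				1	
Giraffa giraffa	giraffe							1						
Loxodonta africana	African elephant						X							X
Hippopotamus amphibius	hippo				1		X					X		10
Rhinocerotidae	white & black rhinoceros										1			
Ovis/Capra	sheep and goats	Caprini	Caprini				X	8		1	4	X	1	402
Aepyceros melampus	impala	Aepycerotini	Aepycerotini				X	13		1	8			1
Alcelaphus caama	hartebeest	Alcelaphini	Alcelaphini	3		5		9			2			
Connochaetes gnou	black wildebeest	Alcelaphini	Alcelaphini	1	5				4				4	
Connochaetes taurinus	blue wildebeest	Alcelaphini	Alcelaphini					14			2			1
Damaliscus pygargus	blesbok/bontebok	Alcelaphini	Alcelaphini	1	2	2		2					4	
Antidorcas marsupialis	springbuck	Antilopini	Antilopini		1					1	4			
Neotragus moschatus	suni	Antilopinae	Neotragini								3			
Oreotragus oreotragus	klipspringer	Oreotragini	Oreotragini	2		6		17	5	18	9		17	
Ourebia ourebi	oribi	Antilopini	Antilopini		6	3		11	4	1	11		22	
Raphicerus campestris	steenbok	Antilopinae	Neotragini	3	1		X	29		10	18		11	
Raphicerus melanotis	grysbok	Antilopini	Antilopini			3			3					
Cephalophus natalensis	red duiker	Cephalophini	Cephalophini	1			X			2	6			
Philantomba monticola	blue duiker	Cephalophini	Cephalophini				X	12		1				11
Sylvicapra grimmia	common duiker	Cephalophini	Cephalophini	2			X	35		4	8	X		24
Hippotragus sp.	roan and/or sable	Hippotragini	Hippotragini					3	1		1		1	
Pelea capreolus	grey rhebuck	Reduncini	Reduncini	8		3		7	5	16	8	X	21	
Kobus ellipsiprymnus	waterbuck	Reduncini	Reduncini								1			
Redunca arundinum	reedbuck	Reduncini	Reduncini	2	5			7			10	X		
Redunca fulvorufula	mountain reedbuck	Reduncini	Reduncini	2		5		25	3	2	10		14	3
Taurotragus oryx	eland	Tragelaphinini	Tragelaphini	8	2	2		13		3	4			
Tragelaphus angasii	nyala	Tragelaphinini	Tragelaphini									X		
Tragelaphus sylvaticus	bushbuck	Tragelaphinini	Tragelaphini					5	1		2			1
Tragelaphus strepsiceros	kudu	Tragelaphinini	Tragelaphini					4			3			
Bos taurus	cattle	Bovini	Bovini			2	X				5	X		38
Syncerus caffer	buffalo	Bovini	Bovini				X	3			1		3	
BOV I				2	7	13	33	12	15	11	5	0	54	10
BOV II				3	6	11	37	30	16	12	10	0	63	6
BOV III				2	14	7	8	16	7	4	7	0	16	5
BOV IV				0	3	5	0	1	3	0	4	0	8	0
Aonyx capensis	clawless otter			2									4	2
Atilax paludinosus	water mongoose						X							
Crocodylus niloticus	crocodile						X					X		
Otolemur crassicaudatus	greater bushbaby						X							
Hystrix africaeaustralis	porcupine			3	2				3	4	6		9	1
Leporidae	hares				5	6			4	4		X	47	4
Struthio camelus	ostrich						X					X		
Varanus niloticus	nile monitor lizard						X							
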