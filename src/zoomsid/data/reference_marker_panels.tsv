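# provenance: source Table 3 - collagen peptide marker panels determined from modern comparative reference specimens (verbatim transcription)
specimen_code	family	subfamily	tribe	species	common_name	A	B	X1	C	X2	D	X3	F	G	X4
NMS.Z.2002.212.5	Bovidae	Antilopinae	Aepycerotini	Aepyceros melampus	Impala	1196	1427		1550		2131	2581	2883	3033	3227
NMS Unregistered	Bovidae	Antilopinae	Alcelaphini	Damaliscus lunatus jimela	Topi	1196	1427		1550		2131	2581	2883	3033	3201
Unregistered	Bovidae	Antilopinae	Alcelaphini	Alcelaphus buselaphus	Hartebeest	1196	1427		1550		2131	2581	2883	3033	3201
NMS.Z.1997.22.118	Bovidae	Antilopinae	Alcelaphini	Connochaetes taurinus	Blue wildebeest	1196	1427		1550		2131	2581	2883	3033	3201
NMS.Z.2002.211.3	Bovidae	Antelopinae	Reduncini	Kobus megaceros	Nile lechwe	1166	1427		1550		2131	2567	2883	3033	3227
NMS Unregistered	Bovidae	Antelopinae	Reduncini	Pelea capreolus	Grey rhebok	1166	1427		1550		2131	2567	2883	3033	3227
NMS.Z.2003.138.1	Bovidae	Antilopinae	Antilopini	Nanger dama	Dama gazelle	1196	1427		1550		2131	2581	2883	3033	3227
NMS.Z.2010.46.43	Bovidae	Antilopinae	Antilopini	Eudorcas (Gazella) rufifrons	Red-fronted gazelle	1196	1427		1550		2131	2581	2883	3033	3227
NMS.Z.1997.22.62	Bovidae	Antilopinae	Antilopini	Litocranius walleri	Gerenuk	1196	1427		1550		2131	2581	2883	3033	3227
NMS Unregistered	Bovidae	Antilopinae	Antilopini	Antidorcas marsupialis	Springbok	1196	1427		1550		2131	2553	2883	3033	3227
NMS.Z.2007.18.2	Bovidae	Antilopinae	Neotragini	Neotragus moschatus	Suni	1196	1427		1580		2131	2581	2883	3033	3227
NMS Unregistered	Bovidae	Antilopinae	Neotragini	Raphicerus campestris	Steenbok	1196	1427		1550		2131	2581	2883	3033	3227
Unregistered	Bovidae	Bovinae	Bovini	Syncerus caffer	African buffalo	1208	1455		1580		2131	2581	2853	3075	
Unregistered	Bovidae	Bovinae	Tragelaphini	Taurotragus oryx	Common eland	1208	1427		1580		2131	2623	2883		
NMS.Z.2011.165.2	Bovidae	Caprinae	Caprini	Ammotragus lervia	Barbary sheep	1196	1427		1580		2131	2581	2883	3033	
NMS.Z.2011.147	Bovidae	Antilopinae	Cephalophini	Philantomba maxwellii	Maxwell’s duiker	1208	1427	1514	1580		2131	2581	2883	3059	
NMS Unregistered	Bovidae	Antilopinae	Cephalophini	Sylvicapra grimmia	Common duiker	1208	1427	1532	1580		2131	2581	2853	3059	
NMS.Z.2000.378.3	Bovidae	Antilopinae	Cephalophini	Cephalophus natalensis	Natal red duiker	1208	1427	1574	1580		2131	2581	2853	3059	
NMS.Z.2005.104.2	Bovidae	Antilopinae	Hippotragini	Addax nasomaculatus	Addaz	1196	1427		1580		2131	2581	2883	3059	
NMS.Z.2001.149.12	Bovidae	Antilopinae	Hippotragini	Hippotragus equinus	Roan antelope	1196	1427		1580		2131	2581	2883	3059	
NMS.Z.2001.22.2	Bovidae	Antilopinae	Hippotragini	Oryx dammah	Scimitar oryx	1196	1427		1580		2131	2581	2883	3059	
NMS.Z.2013.61	Suidae			Potamochoerus porcus	Red river hog	1196	1453		1546	1816/32	2131	2579	2883	3033	
NMS.Z.2012.34.2	Suidae			Phacochoerus africanus	Warthog	1196	1453		1546	1832/48	2131	2579	2883	3033	
NMS.Z.2000.178	Canidae	Caninae		Otocyon megalotis	Bat-eared fox	1226	1427		1590		2131	2611	2853	2999	
NMS.Z.2015.121	Canidae	Caninae		Lycaon pictus	African wild dog	1226	1453		1566		2131	2611	2853	2999	
NMS Unregistered	Canidae	Caninae		Canis aureus	Golden Jackal	1226	1453		1566		2131	2611	2853	2999	
NMS.Z.2014.96.2	Felidae	Felinae		Acinonyx jubatus	Cheetah	1207	1453		1566		2163	2597	2853	2999	
NMS.Z.2004.45	Hyaenidae	Hyaeninae		Hyaena hyaena	Striped hyaena	1207	1453		1566		2147	2597	2853	2999	
NMS.Z.2020.44	Hyaenidae	Protelinae		Proteles cristatus	Aardwolf	1207	1441		1566		2147	2597	2853	2999	
UoM unregistered	Bovidae			Giraffa camelopardalis	Giraffe	1166	1427		1580		2131		2883	3003	
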