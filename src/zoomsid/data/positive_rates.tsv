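# provenance: source Table 4 - number and percentage of sampled specimens per site returning a positive fingerprint (printed values retained for validation)
site	n_positive	pct_printed
Collingham	3	37.5
Driel	2	25
Good Hope	4	40
KwaGandaganda	6	54.5
Maqonqo	2	16.7
Mgede	4	100
Mhlwazini	0	0
Mzinyashana	7	87.5
Ndondondwane	10	83.3
Nkupe	2	33.3
Wozi	3	100
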