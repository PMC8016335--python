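# provenance: source Table 2 - number and percentage of cylindrical bone point shaft fragments sampled per site (printed percentages retained for validation)
site	shaft_fragments	n_sampled	pct_printed
Collingham	86	8	9.3
Driel	14	8	57.1
Good Hope	35	10	28.6
KwaGandaganda	46	11	23.9
Maqonqo	129	12	9.3
Mgede	21	4	19
Mhlwazini	26	2	7.7
Mzinyashana	89	8	8.9
Ndondondwane	12	12	100
Nkupe	51	6	11.8
Wozi	24	3	12.5
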