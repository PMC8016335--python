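# provenance: site roster - settlement type per the study background (farmer settlements vs hunter-gatherer shelters); worked-bone totals from the source Table 5 site headers; Wozi is an alternate spelling of Wosi
site	settlement	aliases	worked_bone_n
Collingham	hunter-gatherer		169
Driel	hunter-gatherer		41
Good Hope	hunter-gatherer		41
KwaGandaganda	farmer		61
Maqonqo	hunter-gatherer		281
Mgede	hunter-gatherer		99
Mhlwazini	hunter-gatherer		53
Mzinyashana	hunter-gatherer		285
Ndondondwane	farmer		12
Nkupe	hunter-gatherer		406
Wosi	farmer	Wozi	24
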