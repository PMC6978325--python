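species	sex	accession	genome_size_bp
Scrobicularia plana	F	MN528026	16170
Scrobicularia plana	M	MN528027	26270
Limecola balthica	F	MN528028	17492
Limecola balthica	M	MN528029	24792
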