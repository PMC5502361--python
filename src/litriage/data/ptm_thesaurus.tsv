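# PTM triage thesaurus: the 16 most frequently curated post-translational modification types.
# columns: concept_id<TAB>label<TAB>stems(pipe-separated; spaces = multi-token stem)<TAB>category
concept_id	label	stems	category
PTM:0001	phosphorylation	phosphorylat	ptm_type
PTM:0002	methylation	methylat	ptm_type
PTM:0003	dephosphorylation	dephosphorylat	ptm_type
PTM:0004	glycosylation	glycosylat	ptm_type
PTM:0005	nitrosylation	nitrosylat	ptm_type
PTM:0006	palmitoylation	palmitoylat	ptm_type
PTM:0007	deubiquitination	deubiquitinat|deubiquitylat	ptm_type
PTM:0008	polyADP-ribosylation	ribosylat	ptm_type
PTM:0009	acetylation	acetylat	ptm_type
PTM:0010	desumoylation	desumoylat	ptm_type
PTM:0011	myristoylation	myristoylat	ptm_type
PTM:0012	deacetylation	deacetylat	ptm_type
PTM:0013	farnesylation	farnesylat	ptm_type
PTM:0014	ubiquitination	ubiquitinat|ubiquitylat	ptm_type
PTM:0015	sumoylation	sumoylat	ptm_type
PTM:0016	protein cleavage	cleav	ptm_type
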