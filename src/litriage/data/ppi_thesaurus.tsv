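# PPI triage thesaurus: 14 stemmed interaction terms + 9 experimental methods (23 concepts).
# RECONSTRUCTION: the interaction stems are built from the named exemplars of the published
# vocabulary (bind, interact, associate, complex, ...) completed to 14 with common PPI trigger
# verbs, and the methods are 9 widely annotated PSI-MI interaction-detection assays. This file
# is NOT the original supplementary vocabulary and should not be cited as such.
# columns: concept_id<TAB>label<TAB>stems(pipe-separated; spaces = multi-token stem)<TAB>category
concept_id	label	stems	category
PPI:0001	bind	bind|bound	interaction_term
PPI:0002	interact	interact	interaction_term
PPI:0003	associate	associat	interaction_term
PPI:0004	complex	complex	interaction_term
PPI:0005	dimerize	dimeriz|dimer	interaction_term
PPI:0006	oligomerize	oligomeriz|oligomer	interaction_term
PPI:0007	colocalize	colocaliz|co localiz	interaction_term
PPI:0008	recruit	recruit	interaction_term
PPI:0009	dock	dock	interaction_term
PPI:0010	tether	tether	interaction_term
PPI:0011	couple	coupl	interaction_term
PPI:0012	attach	attach	interaction_term
PPI:0013	contact	contact	interaction_term
PPI:0014	scaffold	scaffold	interaction_term
PPI:0101	two-hybrid	two hybrid	experimental_method
PPI:0102	pull-down	pull down	experimental_method
PPI:0103	coimmunoprecipitation	coimmunoprecipitat|immunoprecipitat	experimental_method
PPI:0104	tandem affinity purification	tandem affinity purif	experimental_method
PPI:0105	surface plasmon resonance	surface plasmon resonance	experimental_method
PPI:0106	X-ray crystallography	crystallograph	experimental_method
PPI:0107	cross-linking	cross link	experimental_method
PPI:0108	far-western blotting	far western	experimental_method
PPI:0109	fluorescence resonance energy transfer	fret|fluorescence resonance energy transfer	experimental_method
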