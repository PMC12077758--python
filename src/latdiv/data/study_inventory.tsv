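group	species_id	lat_north	lat_south	n_sequences
crab	Acanthonyx petiverii	10	-23	41
crab	Aratus pisonii	27	-23	61
crab	Arenaeus cribrarius	36	-26	44
crab	Armases angustipes	-2	-25	66
crab	Callinectes danae	9	-32	54
crab	Callinectes ornatus	4	-32	44
crab	Eriphia gonagra	10	-23	40
crab	Goniopsis cruentata	20	-25	62
crab	Leptuca leptodactyla	19	-23	86
crab	Leptuca thayeri	27	-27	61
crab	Minuca mordax	2	-29	113
crab	Minuca rapax	28	-25	57
crab	Sesarma rectum	10	-24	42
crab	Uca maracoani	19	-25	103
crab	Ucides cordatus	23	-23	52
hermit_crab	Calcinus tibicen (N)	27	9	36
hermit_crab	Calcinus tibicen (S)	-3	-27	28
hermit_crab	Clibanarius antillensis	18	-26	37
hermit_crab	Clibanarius symmetricus	0	-27	22
hermit_crab	Clibanarius tricolor	25	12	167
shrimp	Hippolyte obliquimanus	10	-27	39
shrimp	Thor amboinensis	32	9	302
lobster	Panulirus argus	26	17	326
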