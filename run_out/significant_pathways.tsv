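class	pathway	omics	pc	score	shared
LTS	PW0004	non-LTS:CNV	2	0.032393005828207165	True
LTS	PW0004	non-LTS:EXP	2	0.026891305746921994	True
LTS	PW0004	LTS:CNV	2	0.02447373555843292	True
LTS	PW0004	LTS:EXP	1	0.021574826118975425	True
LTS	PW0004	non-LTS:CNV	1	0.0204485055086262	True
non-LTS	PW0004	LTS:CNV	2	0.0264217992611887	True
non-LTS	PW0004	non-LTS:CNV	2	0.021540949618186186	True
non-LTS	PW0004	non-LTS:EXP	2	0.01850265487410003	True
non-LTS	PW0004	LTS:EXP	1	0.01708144663157748	True
non-LTS	PW0004	non-LTS:CNV	1	0.016192261650980182	True
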