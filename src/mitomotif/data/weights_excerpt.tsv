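position	mutation	weight
13500	T13500C	1.312
12561	G12561A	1.312
9843	A9843G	1.593
15499	T15499C	1.593
3338	T3338C	1.360
16189	T16189C	0.475
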