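sample	autumn_spawners	spring_spawners	unassigned
North Atlantic (Lofoten)	46	45	6
Kirkefjorden	90	3	1
Austefjorden	48	61	10
Dalsfjorden	28	46	2
Gursken	25	27	16
Hjoerundfjorden	2	109	0
Romsdalsfjorden	25	7	0
Sykkylven	6	124	6
Volda	6	30	3
NSS-Strandfjorden	30	0	0
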