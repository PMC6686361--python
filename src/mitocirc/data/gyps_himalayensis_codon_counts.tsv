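# Pooled codon counts over the 13 protein-coding genes of the Gyps himalayensis
# mitogenome (KY594709), vertebrate mitochondrial code; '*' marks stop codons.
codon	aa	count
UUU	F	188
UUC	F	79
UUA	L	137
UUG	L	14
CUU	L	169
CUC	L	92
CUA	L	144
CUG	L	31
AUU	I	269
AUC	I	83
AUA	M	139
AUG	M	39
GUU	V	63
GUC	V	37
GUA	V	63
GUG	V	18
UCU	S	59
UCC	S	41
UCA	S	137
UCG	S	8
CCU	P	20
CCC	P	54
CCA	P	117
CCG	P	9
ACU	T	69
ACC	T	86
ACA	T	127
ACG	T	8
GCU	A	73
GCC	A	147
GCA	A	94
GCG	A	6
UAU	Y	59
UAC	Y	45
UAA	*	3
UAG	*	1
CAU	H	27
CAC	H	68
CAA	Q	79
CAG	Q	9
AAU	N	64
AAC	N	63
AAA	K	74
AAG	K	8
GAU	D	29
GAC	D	46
GAA	E	64
GAG	E	20
UGU	C	17
UGC	C	10
UGA	W	95
UGG	W	13
CGU	R	13
CGC	R	19
CGA	R	38
CGG	R	4
AGU	S	21
AGC	S	24
AGA	*	1
AGG	*	2
GGU	G	45
GGC	G	69
GGA	G	73
GGG	G	42
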