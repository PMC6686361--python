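# Default control-region motif library, version 1 (provisional).
# The palindromic TACAT/ATGTA motifs are canonical; the conserved-box (F, E, D,
# C) and CSB patterns below are SYNTHETIC placeholder consensi: no published
# box sequences back them, and users analysing real control regions should
# substitute curated species-appropriate patterns. IUPAC ambiguity codes are
# allowed in patterns; strand is 'forward', 'reverse' or 'both'.
name	iupac_pattern	max_mismatch	strand
TACAT	TACAT	0	forward
ATGTA	ATGTA	0	forward
F-box	ATGGYCTAGAAAGCCAGGAC	1	forward
E-box	AGGGAACTCCYTTCTTGACG	1	forward
D-box	CCTGGTTCYTACTTCAGGGT	1	forward
C-box	CGTGCATYAAACTGTCAGCT	1	forward
CSB-a	TTTCAATGCYTGACGGACAT	1	forward
CSB-b	AAACTCCGYTACACGTTCCA	1	forward
CSB-1	TTCTTGACAYCTGGTTCCTA	1	forward
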