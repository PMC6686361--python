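# Annotated feature table of the Gyps himalayensis mitogenome (GenBank KY594709).
# Coordinates are 1-based inclusive on the heavy strand; genome length 17,381 bp.
# Duplicated tRNA names carry suffixes 1/2 in order of appearance.
name	type	start	end	strand
tRNA-Phe	tRNA	1	70	H
12S rRNA	rRNA	71	1055	H
tRNA-Val	tRNA	1037	1108	H
16S rRNA	rRNA	1101	2730	H
tRNA-Leu1	tRNA	2711	2784	H
ND1	PCG	2794	3771	H
tRNA-Ile	tRNA	3770	3841	L
tRNA-Gln	tRNA	3855	3925	H
tRNA-Met	tRNA	3925	3993	H
ND2	PCG	3994	5038	H
tRNA-Trp	tRNA	5039	5110	H
tRNA-Ala	tRNA	5112	5180	L
tRNA-Asn	tRNA	5183	5255	L
tRNA-Cys	tRNA	5258	5324	L
tRNA-Tyr	tRNA	5324	5394	L
COXI	PCG	5396	6946	H
tRNA-Ser1	tRNA	6938	7011	L
tRNA-Asp	tRNA	7016	7084	H
COXII	PCG	7087	7770	H
tRNA-Lys	tRNA	7772	7843	H
ATP8	PCG	7844	8008	H
ATP6	PCG	7999	8682	H
COXIII	PCG	8682	9464	H
tRNA-Gly	tRNA	9466	9534	H
ND3	PCG	9535	9885	H
tRNA-Arg	tRNA	9890	9958	H
ND4L	PCG	9960	10256	H
ND4	PCG	10250	11626	H
tRNA-His	tRNA	11627	11696	H
tRNA-Ser2	tRNA	11698	11762	H
tRNA-Leu2	tRNA	11763	11833	H
ND5	PCG	11834	13648	H
Cytb	PCG	13661	14803	H
tRNA-Thr	tRNA	14806	14873	H
Control region	CR	14874	16075	H
tRNA-Pro	tRNA	16084	16153	L
ND6	PCG	16176	16694	L
tRNA-Glu	tRNA	16692	16762	L
Pseudo-control region	CCR	16763	17381	H
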