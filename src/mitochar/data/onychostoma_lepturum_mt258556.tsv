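# taxon=Onychostoma lepturum
# accession=MT258556
# genome_length=16598
# circular=true
locus	category	strand	start	stop	size	start_codon	stop_codon	anticodon	intergenic
tRNA-Phe	tRNA	H	1	69	69			GAA	0
12S-rRNA	rRNA	H	70	1030	961				0
tRNA-Val	tRNA	H	1031	1102	72			TAC	0
16S-rRNA	rRNA	H	1103	2783	1681				0
tRNA-Leu	tRNA	H	2784	2859	76			TAA	0
ND1	PCG	H	2860	3834	975	ATG	TAA		0
tRNA-Ile	tRNA	H	3840	3911	72			GAT	4
tRNA-Gln	tRNA	L	3910	3980	71			TTG	-2
tRNA-Met	tRNA	H	3983	4051	69			CAT	2
ND2	PCG	H	4052	5096	1045	ATG	T-		0
tRNA-Trp	tRNA	H	5097	5168	72			TCA	0
tRNA-Ala	tRNA	L	5171	5239	69			TGC	2
tRNA-Asn	tRNA	L	5241	5313	73			GTT	1
tRNA-Cys	tRNA	L	5349	5415	67			GCA	35
tRNA-Tyr	tRNA	L	5415	5486	72			GTA	-1
COI	PCG	H	5488	7038	1551	GTG	TAA		1
tRNA-Ser	tRNA	L	7039	7109	71			TGA	0
tRNA-Asp	tRNA	H	7113	7184	72			GTC	3
COII	PCG	H	7197	7887	691	ATG	T-		12
tRNA-Lys	tRNA	H	7888	7963	76			TTT	0
ATP8	PCG	H	7965	8129	165	ATG	TAG		1
ATP6	PCG	H	8123	8805	683	GTG	TA-		-7
COIII	PCG	H	8806	9590	785	ATG	TAA		0
tRNA-Gly	tRNA	H	9591	9662	72			TCC	0
ND3	PCG	H	9663	10011	349	ATG	T-		0
tRNA-Arg	tRNA	H	10012	10081	70			TCG	0
ND4L	PCG	H	10082	10378	297	ATG	TAA		0
ND4	PCG	H	10372	11752	1381	ATG	T-		-7
tRNA-His	tRNA	H	11753	11821	69			GTG	0
tRNA-Ser	tRNA	H	11822	11890	69			GCT	0
tRNA-Leu	tRNA	H	11892	11964	73			TAG	1
ND5	PCG	H	11965	13788	1824	ATG	TAA		0
ND6	PCG	L	13785	14306	522	ATG	TAG		-4
tRNA-Glu	tRNA	L	14307	14375	69			TTC	0
Cytb	PCG	H	14381	15521	1141	ATG	T-		5
tRNA-Thr	tRNA	H	15522	15594	73			TGT	0
tRNA-Pro	tRNA	L	15594	15663	70			TGG	-1
D-loop	control	H	15664	16598	935				0
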