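Gene	Strand	Location	Size	Anticodon	StartCodon	StopCodon	Intergenics
tRNA-Phe	+	1–68	68	GAA			0
12S-rRNA	+	69–1012	944				0
tRNA-Val	+	1013–1083	71	TAC			0
16S-rRNA	+	1084–2761	1678				0
tRNA-Leu(UUR)	+	2762–2836	75	TAA			0
ND1	+	2837–3811	975		ATG	TAG	3
tRNA-Ile	+	3815–3884	70	GAT			-1
tRNA-Gln	−	3884–3954	71	TTG			-1
tRNA-Met	+	3954–4023	70	CAT			1
ND2	+	4025–5146	1122		ATG	TAA	0
NC	+	5147–5181	35
tRNA-Trp	+	5183–5253	71	TCA			2
tRNA-Ala	−	5256–5324	69	TGC			1
tRNA-Asn	−	5326–5398	73	GTT			33
OL	−	5399–5431	33
tRNA-Cys	−	5432–5496	65	GCA			0
tRNA-Tyr	−	5496–5566	71	GTA			1
COX1	+	5569–7122	1554		GTG	TAA	0
tRNA-Ser(UCN)	−	7123–7193	71	TGA			3
tRNA-Asp	+	7197–7268	72	GTC			3
COX2	+	7272–7962	691		ATG	T--	0
tRNA-Lys	+	7963–8036	74	TTT			1
ATP8	+	8038–8202	165		ATG	TAA	-5
ATP6	+	8196–8878	683		ATG	TA-	0
COX3	+	8879–9662	784		ATG	T--	0
tRNA-Gly	+	9663–9734	72	TCC			0
ND3	+	9735–10,083	349		ATG	T--	0
tRNA-Arg	+	10,084–10,152	69	TCG			0
ND4L	+	10,153–10,449	297		ATG	TAA	-5
ND4	+	10,443–11,823	1381		ATG	T--	0
tRNA-His	+	11,824–11,891	68	GTG			0
tRNA-Ser(AGY)	+	11,892–11,959	68	GCT			3
tRNA-Leu(CUN)	+	11,963–12,035	73	TAG			0
ND5	+	12,036–13,874	1839		ATG	TAA	-2
ND6	−	13,871–14,392	522		ATG	TAG	0
tRNA-Glu	−	14,393–14,461	69	TTC			5
CYTB	+	14,467–15,610	1144		ATG	T--	0
tRNA-Thr	+	15,611–15,682	72	TGT			-1
tRNA-Pro	−	15,682–15,751	70	TGG			0
Control region	+	15,752–17,246	1495
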