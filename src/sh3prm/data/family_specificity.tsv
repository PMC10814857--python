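family_id	class_ids	inferred	note
1	RX[LA]PXXP,RXXPXXP,KXX[LA]PXXP,PXXP	no	basic-anchored core motifs
2	XPPX,PXP,PPXPP,PXXP,PXXXP	no	PPXPPXP-type consensus
3	PXXDY,PXXPXLP,PPPXLP,PPPPP	no	D/Y- and L-containing patterns
4	PXXXP,PPXPP	no	PXXXPPXPP-type consensus
5	PXPXXP	no	single specific class
6	RXXPXXP	yes	consensus inferred from RIMBP1/2 vs RIM1/2 ligands; no direct structural or biochemical data
7	PXXPX[KR],[KR]XPXXP,[KR]XXPXXP,PXXPXX[KR],PXXP	no	basic anchor on either side
8	PXXXP,PXXXPR,PXXXPXR	no	wide-spaced pair with optional arginine
9	PXXPX[KR],PXXPX[LP]	no	basic or L/P anchor
10	PX[PA]XXR,PXXPXXP[KR],PXXPX[KR],RXX[KR]P,PPPPP	no	versatile arginine-anchored set
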