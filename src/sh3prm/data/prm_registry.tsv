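class_id	spec	family_links	note
PPPP	PPPP		core proline run
XPPX	XPPX	2	flanked proline pair
PXP	PXP	2	minimal spaced prolines
PXPXP	PXPXP		alternating prolines
PPXPP	PPXPP	2,4	double proline pair
PXXP	PXXP	1,2,7	canonical SH3 core motif
PXXPX[KR]	PXXPX[KR]	7,9,10	core motif with C-terminal basic anchor
[KR]XXPXXP	[KR]XXPXXP	7	core motif with N-terminal basic anchor
PXXPXXP	PXXPXXP		extended triple-proline core
PXXXP	PXXXP	2,4,8	wide-spaced proline pair
PXXXPXXXP	PXXXPXXXP		tandem wide-spaced prolines
PXXXPR	PXXXPR	8	wide-spaced pair with arginine anchor
PXXXXP	PXXXXP		widest-spaced proline pair
PX[PA]XXR	PX[PA]XXR	10	family-10 arginine-anchored class
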