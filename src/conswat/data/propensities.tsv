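residue	atom	h	l
*	N	0.24	0.00
*	O	0.56	0.00
*	OXT	0.90	0.00
*	OG	0.69	0.00
*	OG1	0.61	0.00
*	OH	0.62	0.00
*	OD1	0.79	0.00
*	OD2	0.81	0.00
*	OE1	0.76	0.00
*	OE2	0.79	0.00
*	ND1	0.54	0.00
*	ND2	0.52	0.00
*	NE	0.46	0.00
*	NE1	0.42	0.00
*	NE2	0.51	0.00
*	NH1	0.67	0.00
*	NH2	0.67	0.00
*	NZ	0.79	0.00
*	SD	0.11	0.20
*	SG	0.13	0.20
element	C	0.03	1.00
element	N	0.40	0.00
element	O	0.60	0.00
element	S	0.12	0.20
element	P	0.50	0.00
element	H	0.00	0.00
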