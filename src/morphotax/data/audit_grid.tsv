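id	AODF 0603	AODF 0660	QM F7292	EMF102	AODF 0836	AODF 0663	AODF 0906	AODF 2854	AODF 2296	AODF 0844	AODF 0590	AODF 0591	AODF 2851	AODF 0656	AODF 0665	AODF 0666	AODF 0832	AODF 2306	AODF 0032	EMF164	EMF106	EMF109	EMF165	EMF100	EMF105
D1	O	X	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
D2	O	-	O	O	O	O	-	-	-	O	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
D3	O	-	-	-	-	O	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
D4	O	-	-	O	-	O	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
D5	O	-	-	-	-	-	-	-	-	-	X	-	-	-	-	X	-	-	-	-	-	-	-	-	-
D6	O	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
D7	O	-	-	-	-	-	-	-	-	-	O	-	-	-	O	O	-	-	-	-	-	-	-	-	-
D8	O	X	-	-	-	-	-	-	-	-	-	-	-	-	-	O	-	-	-	-	-	-	-	-	-
S1	-	O	X	-	-	-	X	-	X	-	X	-	-	-	-	-	-	-	X	-	X	-	-	-	-
S2	-	O	X	-	-	-	X	-	X	-	X	-	-	-	-	-	-	-	X	-	X	-	-	-	-
S3	O	O	-	-	-	-	-	-	O	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
S4	-	O	-	-	-	-	-	-	O	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
S5	X	O	X	-	-	-	-	O	X	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
S6	X	O	-	X	X	-	-	-	-	-	-	-	-	-	-	-	-	-	X	-	-	-	-	-	-
S7	X	O	X	X	X	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
S8	X	O	-	-	-	-	-	-	-	-	-	-	-	-	-	X	-	-	-	-	-	-	-	-	-
S9	X	O	-	-	-	-	-	-	-	-	-	-	-	-	-	X	-	-	-	-	-	-	-	-	-
W1	-	X	O	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
W2	-	X	O	-	-	-	X	-	O	-	-	-	-	-	-	-	O	X	X	-	O	-	-	-	-
W3	-	-	O	-	-	-	-	-	O	-	-	X	-	-	-	-	X	X	-	-	-	O	-	-	-
W4	-	-	O	-	-	-	-	-	O	-	-	O	O	-	-	-	O	-	-	-	-	O	-	-	-
W5	X	-	O	-	X	O	-	-	-	O	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
W6	O	O	O	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
W7	X	X	O	-	-	-	-	X	X	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
W8	X	X	O	X	X	-	-	-	-	-	-	-	-	-	-	-	-	-	X	-	-	-	-	-	-
A1	O	-	O	O	-	-	-	-	O	-	-	-	-	O	O	-	-	-	-	O	-	-	-	O	-
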