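name	pattern	ref_base	alt_base	parent
nCg>nTg	ncg	C	T	-
rCg>rTg	rcg	C	T	nCg>nTg
yCg>yTg	ycg	C	T	nCg>nTg
aTn>aCn	atn	T	C	-
aTr>aCr	atr	T	C	aTn>aCn
yCn>yTn	ycn	C	T	-
yCh>yTh	ych	C	T	yCn>yTn
nTt>nCt	ntt	T	C	-
tCw>tTw	tcw	C	T	-
tCw>tGw	tcw	C	G	-
hTg>hCg	htg	T	C	-
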