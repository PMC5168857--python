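symbol	synonyms
rsfA	RsfA
sigF	sigma(F)|sigma F|sigmaF
sigG	sigma(G)|sigma G|sigmaG
ald
sigE	SigE
sigA	sigmaA|SigA
sigK	sigmaK|SigK
gerE	GerE
ykvP
cotX	CotX
nadE
sigB	sigma B|sigmaB|SigB
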