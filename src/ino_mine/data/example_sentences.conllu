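# sent_id = lll-worked-regulation-of-expression
# text = The expression of rsfA is under the control of both sigma(F) and sigma(G).
1	The	the	_	_	_	2	det	_	_
2	expression	expression	_	_	_	8	nsubj	_	_
3	of	of	_	_	_	4	case	_	_
4	rsfA	rsfA	_	_	_	2	nmod:of	_	_
5	is	be	_	_	_	8	cop	_	_
6	under	under	_	_	_	8	case	_	_
7	the	the	_	_	_	8	det	_	_
8	control	control	_	_	_	0	root	_	_
9	of	of	_	_	_	11	case	_	_
10	both	both	_	_	_	11	cc:preconj	_	_
11	sigma(F)	sigma(F)	_	_	_	8	nmod:of	_	_
12	and	and	_	_	_	13	cc	_	_
13	sigma(G)	sigma(G)	_	_	_	11	conj:and	_	_
14	.	.	_	_	_	8	punct	_	_

# sent_id = lll-nsubj-control-expression
# text = The expression of rsfA is under the control of both sigma(F) and sigma(G).
1	The	the	_	_	_	2	det	_	_
2	expression	expression	_	_	_	8	nsubj	_	_
3	of	of	_	_	_	4	case	_	_
4	rsfA	rsfA	_	_	_	2	nmod:of	_	_
5	is	be	_	_	_	8	cop	_	_
6	under	under	_	_	_	8	case	_	_
7	the	the	_	_	_	8	det	_	_
8	control	control	_	_	_	0	root	_	_
9	of	of	_	_	_	11	case	_	_
10	both	both	_	_	_	11	cc:preconj	_	_
11	sigma(F)	sigma(F)	_	_	_	8	nmod:of	_	_
12	and	and	_	_	_	13	cc	_	_
13	sigma(G)	sigma(G)	_	_	_	11	conj:and	_	_
14	.	.	_	_	_	8	punct	_	_

# sent_id = lll-nsubjpass-recognized-promoter
# text = The ald promoter, like the sigE promoter, is believed to be recognized by sigmaA RNA polymerase, suggesting that sigmaK may inhibit sigmaA activity late in sporulation.
1	The	the	_	_	_	3	det	_	_
2	ald	ald	_	_	_	3	compound	_	_
3	promoter	promoter	_	_	_	11	nsubjpass	14:nsubjpass	_
4	,	,	_	_	_	3	punct	_	_
5	like	like	_	_	_	8	case	_	_
6	the	the	_	_	_	8	det	_	_
7	sigE	sigE	_	_	_	8	compound	_	_
8	promoter	promoter	_	_	_	3	nmod:like	_	_
9	,	,	_	_	_	3	punct	_	_
10	is	be	_	_	_	11	auxpass	_	_
11	believed	believe	_	_	_	0	root	_	_
12	to	to	_	_	_	14	mark	_	_
13	be	be	_	_	_	14	auxpass	_	_
14	recognized	recognize	_	_	_	11	xcomp	_	_
15	by	by	_	_	_	18	case	_	_
16	sigmaA	sigmaA	_	_	_	18	compound	_	_
17	RNA	RNA	_	_	_	18	compound	_	_
18	polymerase	polymerase	_	_	_	14	nmod:agent	_	_
19	,	,	_	_	_	11	punct	_	_
20	suggesting	suggest	_	_	_	11	advcl	_	_
21	that	that	_	_	_	24	mark	_	_
22	sigmaK	sigmaK	_	_	_	24	nsubj	_	_
23	may	may	_	_	_	24	aux	_	_
24	inhibit	inhibit	_	_	_	20	ccomp	_	_
25	sigmaA	sigmaA	_	_	_	26	compound	_	_
26	activity	activity	_	_	_	24	dobj	_	_
27	late	late	_	_	_	24	advmod	_	_
28	in	in	_	_	_	29	case	_	_
29	sporulation	sporulation	_	_	_	27	nmod:in	_	_
30	.	.	_	_	_	11	punct	_	_

# sent_id = lll-dobj-inhibit-activity
# text = The ald promoter, like the sigE promoter, is believed to be recognized by sigmaA RNA polymerase, suggesting that sigmaK may inhibit sigmaA activity late in sporulation.
1	The	the	_	_	_	3	det	_	_
2	ald	ald	_	_	_	3	compound	_	_
3	promoter	promoter	_	_	_	11	nsubjpass	14:nsubjpass	_
4	,	,	_	_	_	3	punct	_	_
5	like	like	_	_	_	8	case	_	_
6	the	the	_	_	_	8	det	_	_
7	sigE	sigE	_	_	_	8	compound	_	_
8	promoter	promoter	_	_	_	3	nmod:like	_	_
9	,	,	_	_	_	3	punct	_	_
10	is	be	_	_	_	11	auxpass	_	_
11	believed	believe	_	_	_	0	root	_	_
12	to	to	_	_	_	14	mark	_	_
13	be	be	_	_	_	14	auxpass	_	_
14	recognized	recognize	_	_	_	11	xcomp	_	_
15	by	by	_	_	_	18	case	_	_
16	sigmaA	sigmaA	_	_	_	18	compound	_	_
17	RNA	RNA	_	_	_	18	compound	_	_
18	polymerase	polymerase	_	_	_	14	nmod:agent	_	_
19	,	,	_	_	_	11	punct	_	_
20	suggesting	suggest	_	_	_	11	advcl	_	_
21	that	that	_	_	_	24	mark	_	_
22	sigmaK	sigmaK	_	_	_	24	nsubj	_	_
23	may	may	_	_	_	24	aux	_	_
24	inhibit	inhibit	_	_	_	20	ccomp	_	_
25	sigmaA	sigmaA	_	_	_	26	compound	_	_
26	activity	activity	_	_	_	24	dobj	_	_
27	late	late	_	_	_	24	advmod	_	_
28	in	in	_	_	_	29	case	_	_
29	sporulation	sporulation	_	_	_	27	nmod:in	_	_
30	.	.	_	_	_	11	punct	_	_

# sent_id = lll-amod-dependent-transcription
# text = These results demonstrate that sigmaK-dependent transcription of gerE initiates a negative feedback loop in which GerE acts as a repressor to limit production of sigmaK.
1	These	these	_	_	_	2	det	_	_
2	results	result	_	_	_	3	nsubj	_	_
3	demonstrate	demonstrate	_	_	_	0	root	_	_
4	that	that	_	_	_	9	mark	_	_
5	sigmaK-dependent	sigmaK-dependent	_	_	_	6	amod	_	_
6	transcription	transcription	_	_	_	9	nsubj	_	_
7	of	of	_	_	_	8	case	_	_
8	gerE	gerE	_	_	_	6	nmod:of	_	_
9	initiates	initiate	_	_	_	3	ccomp	_	_
10	a	a	_	_	_	13	det	_	_
11	negative	negative	_	_	_	13	amod	_	_
12	feedback	feedback	_	_	_	13	compound	_	_
13	loop	loop	_	_	_	9	dobj	_	_
14	in	in	_	_	_	15	case	_	_
15	which	which	_	_	_	17	nmod	_	_
16	GerE	GerE	_	_	_	17	nsubj	_	_
17	acts	act	_	_	_	13	acl:relcl	_	_
18	as	as	_	_	_	20	case	_	_
19	a	a	_	_	_	20	det	_	_
20	repressor	repressor	_	_	_	17	nmod:as	_	_
21	to	to	_	_	_	22	mark	_	_
22	limit	limit	_	_	_	17	advcl	_	_
23	production	production	_	_	_	22	dobj	_	_
24	of	of	_	_	_	25	case	_	_
25	sigmaK	sigmaK	_	_	_	23	nmod:of	_	_
26	.	.	_	_	_	3	punct	_	_

# sent_id = lll-nmod-essential-expression
# text = Both SigK and GerE were essential for ykvP expression, and this gene was transcribed from T5 of sporulation.
1	Both	both	_	_	_	2	cc:preconj	_	_
2	SigK	SigK	_	_	_	6	nsubj	_	_
3	and	and	_	_	_	4	cc	_	_
4	GerE	GerE	_	_	_	2	conj:and	_	_
5	were	be	_	_	_	6	cop	_	_
6	essential	essential	_	_	_	0	root	_	_
7	for	for	_	_	_	9	case	_	_
8	ykvP	ykvP	_	_	_	9	compound	_	_
9	expression	expression	_	_	_	6	nmod:for	_	_
10	,	,	_	_	_	6	punct	_	_
11	and	and	_	_	_	15	cc	_	_
12	this	this	_	_	_	13	det	_	_
13	gene	gene	_	_	_	15	nsubjpass	_	_
14	was	be	_	_	_	15	auxpass	_	_
15	transcribed	transcribe	_	_	_	6	conj:and	_	_
16	from	from	_	_	_	17	case	_	_
17	T5	T5	_	_	_	15	nmod:from	_	_
18	of	of	_	_	_	19	case	_	_
19	sporulation	sporulation	_	_	_	17	nmod:of	_	_
20	.	.	_	_	_	6	punct	_	_

# sent_id = lll-indirect-binds-promoters
# text = GerE binds to a site on one of these promoters, cotX, that overlaps its -35 region.
1	GerE	GerE	_	_	_	2	nsubj	_	_
2	binds	bind	_	_	_	0	root	_	_
3	to	to	_	_	_	5	case	_	_
4	a	a	_	_	_	5	det	_	_
5	site	site	_	_	_	2	nmod:to	_	_
6	on	on	_	_	_	7	case	_	_
7	one	one	_	_	_	5	nmod:on	_	_
8	of	of	_	_	_	10	case	_	_
9	these	these	_	_	_	10	det	_	_
10	promoters	promoter	_	_	_	7	nmod:of	_	_
11	,	,	_	_	_	10	punct	_	_
12	cotX	cotX	_	_	_	10	appos	_	_
13	,	,	_	_	_	12	punct	_	_
14	that	that	_	_	_	15	nsubj	_	_
15	overlaps	overlap	_	_	_	10	acl:relcl	_	_
16	its	its	_	_	_	18	nmod:poss	_	_
17	-35	-35	_	_	_	18	amod	_	_
18	region	region	_	_	_	15	dobj	_	_
19	.	.	_	_	_	2	punct	_	_
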