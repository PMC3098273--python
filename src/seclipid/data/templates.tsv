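type_letter	gene_slot	domain_kind	acp_min	acp_max	fully_specified
A	pfaA	KS	NA	NA	1
A	pfaA	MAT	NA	NA	1
A	pfaA	ACP	4	6	1
A	pfaA	KR	NA	NA	1
A	pfaB	AT	NA	NA	1
A	pfaC	KS	NA	NA	1
A	pfaC	CLF	NA	NA	1
A	pfaC	DH	NA	NA	1
A	pfaC	DH	NA	NA	1
A	pfaD	ER	NA	NA	1
A	pfaE	PPTase	NA	NA	1
B	pfaA	KS	NA	NA	1
B	pfaA	MAT	NA	NA	1
B	pfaA	ACP	4	6	1
B	pfaA	KR	NA	NA	1
B	pfaB	KS	NA	NA	1
B	pfaB	AT	NA	NA	1
B	pfaC	KS	NA	NA	1
B	pfaC	CLF	NA	NA	1
B	pfaC	DH	NA	NA	1
B	pfaC	DH	NA	NA	1
B	pfaD	ER	NA	NA	1
B	pfaE	PPTase	NA	NA	1
C	pfaA	KS	NA	NA	1
C	pfaA	MAT	NA	NA	1
C	pfaA	ACP	4	6	1
C	pfaA	KR	NA	NA	1
C	pfaBC	KS	NA	NA	1
C	pfaBC	CLF	NA	NA	1
C	pfaBC	AT	NA	NA	1
C	pfaBC	DH	NA	NA	1
C	pfaBC	DH	NA	NA	1
C	pfaE	PPTase	NA	NA	1
C	pfaD	ER	NA	NA	1
D	pfaA1	KS	NA	NA	1
D	pfaA1	AT	NA	NA	1
D	pfaA1	ACP	5	5	1
D	pfaA2	KR	NA	NA	1
D	pfaBC	KS	NA	NA	1
D	pfaBC	CLF	NA	NA	1
D	pfaBC	AT	NA	NA	1
D	pfaBC	DH	NA	NA	1
D	pfaBC	DH	NA	NA	1
D	pfaD	ER	NA	NA	1
D	pfaE	PPTase	NA	NA	1
E	PFA1	KS	NA	NA	1
E	PFA1	MAT	NA	NA	1
E	PFA1	ACP	5	9	1
E	PFA1	KR	NA	NA	1
E	PFA2	KS	NA	NA	1
E	PFA2	CLF	NA	NA	1
E	PFA2	AT	NA	NA	1
E	PFA2	ER	NA	NA	1
E	PFA3	DH	NA	NA	1
E	PFA3	DH	NA	NA	1
E	PFA3	ER	NA	NA	1
F	hglE	KS	NA	NA	1
F	hglE	MAT	NA	NA	1
F	hglE	ACP	4	6	1
F	hglE	KR	NA	NA	1
F	hglC	KS	NA	NA	1
F	hglC	CLF	NA	NA	1
F	hglC	AT	NA	NA	1
F	hglD	ER	NA	NA	1
F	hglP	PPTase	NA	NA	1
H	pfaA1	KS	NA	NA	1
H	pfaA1	MAT	NA	NA	1
H	pfaA1	ACP	4	6	1
H	pfaA2	KR	NA	NA	1
H	pfaBC	KS	NA	NA	1
H	pfaBC	CLF	NA	NA	1
H	pfaBC	AT	NA	NA	1
H	pfaBC	DH	NA	NA	1
H	pfaBC	DH	NA	NA	1
I	pfaA	KS	NA	NA	1
I	pfaA	MAT	NA	NA	1
I	pfaA	ACP	3	5	1
I	pfaA	KR	NA	NA	1
I	pfaBC	KS	NA	NA	1
I	pfaBC	CLF	NA	NA	1
I	pfaBC	DH	NA	NA	1
I	pfaBC	DH	NA	NA	1
I	pfaD	ER	NA	NA	1
I	pfaE	PPTase	NA	NA	1
J	pfaD	ER	NA	NA	1
J	pfaA	KS	NA	NA	1
J	pfaA	MAT	NA	NA	1
J	pfaA	ACP	3	3	1
J	pfaA	KR	NA	NA	1
K	pfaD	ER	NA	NA	1
K	pfaA	KS	NA	NA	1
K	pfaA	MAT	NA	NA	1
K	pfaA	ACP	2	4	1
K	pfaA	KR	NA	NA	1
K	pfaBC	KS	NA	NA	1
K	pfaBC	CLF	NA	NA	1
K	pfaBC	DH	NA	NA	1
L	pfaD	ER	NA	NA	1
L	pfaA	KS	NA	NA	1
L	pfaA	MAT	NA	NA	1
L	pfaA	ACP	3	5	1
L	pfaA	KR	NA	NA	1
L	pfaBC	KS	NA	NA	1
L	pfaBC	CLF	NA	NA	1
L	pfaBC	DH	NA	NA	1
L	pfaBC	DH	NA	NA	1
L	pfaBC	AT	NA	NA	1
L	pfaE	PPTase	NA	NA	1
R	pfaA	KS	NA	NA	1
R	pfaA	MAT	NA	NA	1
R	pfaA	CLF	NA	NA	1
R	pfaA	ACP	3	6	1
R	pfaA	KR	NA	NA	1
R	pfaE	PPTase	NA	NA	1
G	geneA	KS	NA	NA	0
G	geneA	MAT	NA	NA	0
G	geneA	ACP	1	2	0
G	geneA	KR	NA	NA	0
G	geneBC	KS	NA	NA	0
G	geneBC	CLF	NA	NA	0
G	geneBC	AT	NA	NA	0
G	geneBC	DH	NA	NA	0
G	geneBC	DH	NA	NA	0
G	geneD	ER	NA	NA	0
M	geneA	KS	NA	NA	0
M	geneA	ACP	1	3	0
M	geneA	KR	NA	NA	0
M	geneBC	KS	NA	NA	0
M	geneBC	CLF	NA	NA	0
M	geneBC	AT	NA	NA	0
M	geneBC	DH	NA	NA	0
M	geneBC	DH	NA	NA	0
M	geneD	ER	NA	NA	0
M	geneE	PPTase	NA	NA	0
N	geneA	KS	NA	NA	0
N	geneA	MAT	NA	NA	0
N	geneA	ACP	2	3	0
N	geneA	KR	NA	NA	0
N	geneBC	KS	NA	NA	0
N	geneBC	CLF	NA	NA	0
N	geneBC	DH	NA	NA	0
N	geneBC	AT	NA	NA	0
N	geneE	PPTase	NA	NA	0
O	geneA	KS	NA	NA	0
O	geneA	MAT	NA	NA	0
O	geneA	ACP	1	2	0
O	geneA	KR	NA	NA	0
O	geneA	ER	NA	NA	0
O	geneBC	KS	NA	NA	0
O	geneBC	CLF	NA	NA	0
O	geneBC	AT	NA	NA	0
O	geneE	PPTase	NA	NA	0
P	geneA	KS	NA	NA	0
P	geneA	MAT	NA	NA	0
P	geneA	ACP	1	1	0
P	geneA	KR	NA	NA	0
P	geneBC	KS	NA	NA	0
P	geneBC	CLF	NA	NA	0
P	geneBC	DH	NA	NA	0
P	geneBC	DH	NA	NA	0
P	geneBC	AT	NA	NA	0
P	geneD	ER	NA	NA	0
P	geneE	PPTase	NA	NA	0
Q	geneA	KS	NA	NA	0
Q	geneA	MAT	NA	NA	0
Q	geneA	ACP	1	1	0
Q	geneA	KR	NA	NA	0
Q	geneBC	KS	NA	NA	0
Q	geneBC	CLF	NA	NA	0
Q	geneBC	DH	NA	NA	0
Q	geneBC	AT	NA	NA	0
Q	geneD	ER	NA	NA	0
S	geneA	KS	NA	NA	0
S	geneA	ACP	1	2	0
S	geneA	KR	NA	NA	0
S	geneBC	KS	NA	NA	0
S	geneBC	CLF	NA	NA	0
S	geneBC	DH	NA	NA	0
S	geneD	ER	NA	NA	0
S	geneE	PPTase	NA	NA	0
T	geneA	KS	NA	NA	0
T	geneA	MAT	NA	NA	0
T	geneA	ACP	1	2	0
T	geneA	KR	NA	NA	0
T	geneBC	KS	NA	NA	0
T	geneBC	CLF	NA	NA	0
T	geneBC	AT	NA	NA	0
T	geneE	PPTase	NA	NA	0
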