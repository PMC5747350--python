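AtorvaEx	1	AtorvaIn
T09Ex	1	T09In
GWEx	1	GWIn
AtorvaIn	1	OHAtorvaIn
AtorvaIn	1	AtorvaLactoneIn
GWIn	1	OHGWIn
CholER	-1	SREBP
HC25	-1	SREBP
SREBP1	-1	SREBP
SREBP	1	and1
siSREBF1	-1	and1
and1	1	SREBP1
LXR	1	SREBP1
SREBP	1	and2
siSREBF2	-1	and2
and2	1	SREBP2
T09In	1	LXR
GWIn	1	LXR
SREBP2	1	HMGCR
SREBP2	1	and3
siHMGCS1	-1	and3
and3	1	HMGCS1
SREBP2	1	ACAT2
SREBP2	1	ACLY
SREBP2	1	ACSS2
SREBP2	1	MVD
SREBP2	1	IDI1
SREBP2	1	FDPS
SREBP2	1	FDFT1
LXR	1	FDFT1
SREBP2	1	LSS
SREBP2	1	NSDHL
SREBP1	1	FASN
LXR	1	FASN
SREBP1	1	ACSL3
LXR	1	ACSL3
LXR	1	DLAT
LXR	1	ABCA1
SREBP2	1	and4
siLDLR	-1	and4
and4	1	LDLR
SREBP2	1	and5
siNPC1	-1	and5
and5	1	NPC1
ACAT2	1	ACAT2act
HMGCS1	1	HMGCS1act
AcetylCoA	1	AcetylCoA
ACAT2act	1	and6
AcetylCoA	1	and6
AcetylCoA	1	and6
and6	1	AcAcCoA
HMGCS1act	1	and7
AcetylCoA	1	and7
AcAcCoA	1	and7
and7	1	HMGCoA
HMGCoA	1	and8
HMGCR	1	and8
AtorvaIn	-1	and8
and8	1	Mevalonate
Mevalonate	1	CholER
CholMedia	1	and9
LDLR	1	and9
NPC1	1	and9
and9	1	CholER
AcetylCoA	-1	AcetylCoA
CholER	-1	CholER
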