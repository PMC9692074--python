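gene	hgvs_c	hgvs_p	flags	clinvar	hgmd	acmg_codes	ac_Korean	an_Korean	hom_Korean	ac_EastAsian	an_EastAsian	hom_EastAsian	ac_African	an_African	hom_African	ac_Latino	an_Latino	hom_Latino	ac_AshkenaziJewish	an_AshkenaziJewish	hom_AshkenaziJewish	ac_EuropeanFinnish	an_EuropeanFinnish	hom_EuropeanFinnish	ac_EuropeanNonFinnish	an_EuropeanNonFinnish	hom_EuropeanNonFinnish	ac_Other	an_Other	hom_Other	ac_SouthAsian	an_SouthAsian	hom_SouthAsian
PRF1	c.65del	p.Pro22ArgfsTer29		Pathogenic	DM	PVS1;PM2;PP5	2	3816	0	3	17912	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
PRF1	c.160C>T	p.Arg54Cys		Likely pathogenic	DM	PS3;PM2;PP3	0		0	2	18342	0	0		0	4	34472	0	0		0	0		0	1	112048	0	0		0	2	30494	0
PRF1	c.673C>T	p.Arg225Trp		Likely pathogenic	DM	PS3;PM2;PP3	0		0	1	18386	0	0		0	0		0	0		0	0		0	2	112300	0	0		0	0		0
PRF1	c.1066C>T	p.Arg356Trp		Likely pathogenic	DM	PS3;PM2;PP3	0		0	1	18320	0	0		0	0		0	0		0	0		0	2	112044	0	0		0	0		0
PRF1	c.1090_1091del	p.Leu364GlufsTer93		Pathogenic	DM	PVS1;PM2;PP5	3	3816	0	3	18274	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
PRF1	c.1168C>T	p.Arg390Ter		Pathogenic	DM	PVS1;PM2;PP5	1	3810	0	1	18278	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
PRF1	c.1244C>G	p.Ala415Gly		Pathogenic/Likely pathogenic	DM	PM1;PM2;PP3;PP5	0		0	2	18346	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
PRF1	c.1349C>T	p.Thr450Met		Likely pathogenic	DM	PS3;PM2;PP3	0		0	1	18392	0	0		0	0		0	0		0	0		0	1	113486	0	0		0	5	30616	0
UNC13D	c.247C>T	p.Arg83Ter		Pathogenic	DM	PVS1;PM2;PP5	1	3818	0	1	18348	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
UNC13D	c.754-1G>C			Pathogenic	DM	PVS1;PM2;PP5	3	3810	0	3	18364	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
UNC13D	c.1055+1G>A			Pathogenic	DM	PVS1;PM2;PP5	1	3818	0	1	18382	0	0		0	0		0	0		0	1	21566	0	0		0	0		0	0		0
UNC13D	c.1358del	p.Pro453HisfsTer6		Pathogenic	DM	PVS1;PM2;PP5	0		0	1	18384	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
UNC13D	c.2054_2055del	p.Ser685PhefsTer19		Pathogenic	DM	PVS1;PM2;PP5	0		0	1	18382	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
UNC13D	c.2972del	p.Pro991ArgfsTer38		Pathogenic	DM	PVS1;PM2;PP5	0		0	1	17792	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
UNC13D	c.3193C>T	p.Arg1065Ter		Pathogenic	DM	PVS1;PM2;PP5	0		0	1	14058	0	0		0	1	28212	0	0		0	0		0	0		0	0		0	0		0
STX11	c.59del	p.Pro20GlnfsTer43		Pathogenic	DM	PVS1;PM2;PP5	0		0	1	18390	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
STX11	c.496G>T	p.Glu166Ter		Pathogenic	DM	PVS1;PM2;PP5	0		0	1	18342	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
STXBP2	c.577A>C	p.Lys193Gln		Likely pathogenic	DM	PS3;PM2;PP3	1	2098	0	1	11504	0	0		0	0		0	0		0	0		0	1	61452	0	0		0	0		0
STXBP2	c.1214G>A	p.Arg405Gln		Pathogenic/Likely pathogenic	DM	PM1;PM2;PP3;PP5	0		0	4	18342	0	0		0	0		0	0		0	0		0	0		0	0		0	0		0
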