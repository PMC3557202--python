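# clamp PP1 1
ATF4	activate	ATF4	2
ATF4	activate	GADD34	22
Ca	activate	CaM	0
CaM	activate	CREB1	0
GADD34	activate	PP1	0
PA	activate	Ca	0
PA	activate	PACT	0
PA	activate	PERK	5
PA	activate	PKA	35
PA	activate	Ras	0
PA	activate	TRBP	8
PA	activate	p38	0
PA	activate	p58IPK	15
PACT	activate	PKR	0
PERK	activate	eIF2a	0
PKA	activate	CREB1	0
PKA	inhibit	PP2A	0
PKR	activate	eIF2a	0
PP1	inhibit	eIF2a	0
PP2A	inhibit	CREB1	0
Ras	activate	CREB1	0
TRBP	inhibit	PKR	0
eIF2a	activate	ATF4	1
p38	activate	CREB1	0
p58IPK	inhibit	PERK	0
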