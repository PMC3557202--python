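ATF4	activate	GADD34	0
Ca	activate	CaM	0
CaM	activate	CREB1	0
GADD34	activate	PP1	0
PA	activate	Ca	0
PA	activate	PERK	0
PA	activate	PKA	0
PA	activate	Ras	0
PA	activate	p38	0
PA	activate	p58IPK	0
PERK	activate	eIF2a	0
PKA	activate	CREB1	0
PKA	inhibit	PP2A	0
PP1	inhibit	eIF2a	0
PP2A	inhibit	CREB1	0
Ras	activate	CREB1	0
eIF2a	activate	ATF4	0
p38	activate	CREB1	0
p58IPK	inhibit	PERK	0
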