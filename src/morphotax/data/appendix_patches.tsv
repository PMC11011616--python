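otu	character	old	new
Alamosaurus	176	1	0
Malawisaurus	176	1	0
Xianshanosaurus	176	1	?
Savannasaurus_elliottorum	176	1	0
Australotitan_cooperensis	36	0	?
Australotitan_cooperensis	37	1	?
Australotitan_cooperensis	43	0	?
Australotitan_cooperensis	50	0	1
Australotitan_cooperensis	51	2	1
Australotitan_cooperensis	58	1	?
Australotitan_cooperensis	62	1	0
Australotitan_cooperensis	217	0	?
Australotitan_cooperensis	223	0	?
Australotitan_cooperensis	229	1	?
Australotitan_cooperensis	258	1	?
Australotitan_cooperensis	279	0	?
Australotitan_cooperensis	364	0	?
Australotitan_cooperensis	366	0	?
Australotitan_cooperensis	372	1	0
Australotitan_cooperensis	511	?	0
Australotitan_cooperensis	513	0	1
Australotitan_cooperensis	514	1	?
Australotitan_cooperensis	516	0	?
Australotitan_cooperensis	517	0	?
Australotitan_cooperensis	535	1	?
Diamantinasaurus_matildae	394	0	1
Wintonotitan_wattsi	45	0	?
Wintonotitan_wattsi	46	1	?
Wintonotitan_wattsi	192	1	0&1
Wintonotitan_wattsi	206	0	?
Wintonotitan_wattsi	217	0	1
Wintonotitan_wattsi	228	0	?
Wintonotitan_wattsi	236	1	?
Wintonotitan_wattsi	239	1	?
Wintonotitan_wattsi	249	0	?
Wintonotitan_wattsi	252	0	?
Wintonotitan_wattsi	282	0	?
Wintonotitan_wattsi	284	0	1
Wintonotitan_wattsi	358	0	?
Wintonotitan_wattsi	376	0	?
Wintonotitan_wattsi	513	0	1
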