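locus_tag	gene	direction
llmg_1447		positive
llmg_0085		positive
llmg_1770	noxC	positive
llmg_1641	butA	positive
llmg_0339	dar	positive
llmg_2448	pgi	negative
llmg_1094		positive
llmg_0003	rexB	positive
llmg_0885	proB	positive
llmg_0557	prfA	positive
llmg_1775	cysK	positive
llmg_0519	tig	negative
llmg_0960		positive
llmg_0402	pbp1B	positive
llmg_0755		positive
llmg_0959		positive
llmg_1928	kinG	positive
llmg_1095		positive
llmg_1494		positive
llmg_1051		negative
llmg_1776	metC	positive
llmg_0485		positive
llmg_0592		positive
llmg_1317		positive
llmg_0403	pepA	negative
llmg_1957		negative
llmg_1093		positive
llmg_2047		negative
llmg_0556		positive
llmg_0909	kinA	negative
llmg_1642	butB	positive
llmg_0870		negative
llmg_1181	ilvE	negative
llmg_1830	menX	positive
llmg_0487		positive
llmg_0066	araT	negative
llmg_1961	tenA	negative
llmg_1387		negative
llmg_1091		positive
llmg_1582		negative
llmg_0722	serS	negative
llmg_1985	pepO2	negative
llmg_0205		negative
llmg_2035	gidA	positive
llmg_1098	glpD	positive
llmg_1638	mleS	positive
llmg_1128		positive
llmg_0908	llrA	negative
llmg_0760		positive
llmg_2039		positive
llmg_0383	ppnK	positive
llmg_1096		positive
llmg_1090		positive
llmg_1031	trpG	positive
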