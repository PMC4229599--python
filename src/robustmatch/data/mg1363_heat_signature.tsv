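locus_tag	gene	direction
llmg_1775	cysK	positive
llmg_1776	metC	positive
llmg_0091	cysD	positive
llmg_1150		negative
llmg_1494		positive
llmg_0488		positive
llmg_1718	uvrC	positive
llmg_1094		positive
llmg_0199	feoB	positive
llmg_1388		negative
llmg_1042	trpA	positive
llmg_0346	fhuC	positive
llmg_0883		positive
llmg_1503		negative
llmg_1662	uspA	positive
llmg_0428	fni	positive
llmg_1985	pepO2	negative
llmg_1275	aldB	negative
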