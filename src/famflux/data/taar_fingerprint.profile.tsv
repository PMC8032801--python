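# Default fingerprint profile. The anchor is a SYNTHETIC reference
# sequence (not a biological one): random background carrying the
# conserved TM7 block (columns 86-97), the conserved motif scaffold at
# columns 100-113 with the TAAR-defining critical pair (Y at 108, W at
# 112), and the conserved C-terminal cap (columns 114-119). Rules are
# evaluated top to bottom; '?' matches any residue not captured by an
# earlier rule.
anchor	MIINLAAQFGLRDSTFMIGDKTDCFACQWPLEHTLYGCAAKTEEEAMRFLKPKWHISVEGKFSLRSATYSHEEVQKNEQAFMQFYAFVLWLPYFIVATRRNSAVNPLIYGALWFERAKSF
motif	100
motif	101
motif	102
motif	103
motif	104
motif	105
motif	106
motif	107
motif	108
motif	109
motif	110
motif	111
motif	112
motif	113
critical	108	1
critical	112	2
rule	YW	TAAR
rule	NS	TARL_JAWED
rule	N?	NON_TAAR
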