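# Class II taar / tarl gene counts in 76 aquatic vertebrate species,
# transcribed as printed in the published repertoire table.
# Known text/table discrepancies (e.g. channel catfish taar13) are preserved
# as printed in the table.
species	tarl	taar12	taar13	other
Cm	1	0	0	3
Le	1	0	0	1
Lec	51	0	0	0
Pm	32	0	0	0
Rt	2	0	0	4
Lo	1	3	1	1
Aa	1	7	5	0
Aj	2	9	9	0
Am	1	3	1	0
Ar	2	13	8	0
Cc	2	15	5	0
Ch	1	0	1	0
Dr	1	12	5	0
El	2	0	1	0
Ip	1	2	8	0
Lw	1	1	2	0
Pp	1	5	2	0
Pyn	1	5	4	0
Sa	2	4	5	0
Sf	2	0	4	0
Sg	1	6	5	0
Sr	2	7	7	0
Ss	3	0	3	0
Af	1	0	2	0
Bp	1	0	0	0
Cr	1	0	0	0
Cs	1	0	0	0
Dl	1	0	2	0
Ga	1	0	1	0
Gm	2	0	3	0
Hc	1	0	0	0
Lac	2	0	2	0
Lb	1	0	4	0
Lc	1	0	3	0
Mim	1	0	0	0
Moa	1	0	0	0
Mom	1	0	0	0
Ms	1	0	1	0
Nc	0	0	0	0
Pa	1	0	0	0
Pem	1	0	0	0
Po	1	0	0	0
Ps	1	0	0	0
Py	1	0	0	0
Sea	1	0	3	0
Sem	1	0	2	0
Ser	1	0	2	0
Ses	1	0	1	0
Sh	1	0	0	0
Sn	1	0	1	0
Tf	0	0	0	0
Tn	1	0	0	0
To	2	0	0	0
Tr	1	0	0	0
Ac	1	0	0	0
Al	1	0	0	0
Cn	1	0	0	0
Cv	1	0	0	0
Fh	1	0	0	0
Hb	1	0	0	0
Km	1	0	0	0
Mc	1	0	0	0
Mz	1	0	0	0
Nb	1	0	0	0
Nf	1	0	0	0
Ol	1	0	0	0
On	1	0	0	0
Pf	1	0	0	0
Pl	1	0	0	0
Pom	1	0	0	0
Pr	1	0	0	0
Pun	1	0	0	0
Stp	1	0	0	0
Xc	1	0	0	0
Xh	0	0	0	0
Xm	1	0	0	0
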