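group,gene,genorm,normfinder,bestkeeper,deltact,published_consensus
Control,CDC25,1,8,4,6,3.72
Control,EF1-a,1,9,6,8,4.56
Control,Actin,3,5,1,5,2.94
Control,UBC,4,4,2,3,3.13
Control,GAPDH,5,2,3,2,2.78
Control,TUA,6,1,7,1,2.55
Control,SAND,7,3,8,4,5.09
Control,PP2A,8,6,5,7,6.40
Control,TUB,9,7,9,9,8.45
Control,18S,10,10,10,10,10.00
SA,CDC25,1,3,2,3,2.06
SA,EF1-a,1,1,3,1,1.32
SA,PP2A,3,5,5,5,4.40
SA,UBC,4,4,6,4,4.43
SA,GAPDH,5,2,1,2,2.11
SA,Actin,6,6,4,6,5.42
SA,TUA,7,7,7,7,7.00
SA,SAND,8,8,8,8,8.00
SA,TUB,9,9,9,9,9.00
SA,18S,10,10,10,10,10.00
MeJA,Actin,1,4,4,3,2.63
MeJA,EF1-a,1,6,5,5,3.50
MeJA,PP2A,3,7,6,6,5.24
MeJA,UBC,4,1,1,1,1.41
MeJA,TUA,5,2,3,2,2.78
MeJA,18S,6,5,7,7,6.19
MeJA,CDC25,7,8,8,8,7.74
MeJA,GAPDH,8,3,2,4,3.72
MeJA,SAND,9,9,9,9,9.00
MeJA,TUB,10,10,10,10,10.00
ETH,CDC25,1,3,3,3,2.28
ETH,PP2A,1,2,2,2,1.68
ETH,Actin,3,1,1,1,1.32
ETH,TUB,4,4,6,4,4.43
ETH,TUA,5,5,8,5,5.62
ETH,GAPDH,6,6,5,6,5.73
ETH,SAND,7,7,7,7,7.00
ETH,18S,8,8,4,8,6.73
ETH,UBC,9,9,10,9,9.24
ETH,EF1-a,10,10,9,10,9.74
ABA,Actin,1,3,7,1,2.14
ABA,EF1-a,1,5,8,5,3.76
ABA,TUA,3,7,9,7,6.03
ABA,SAND,4,1,5,2,2.51
ABA,TUB,5,2,4,3,3.31
ABA,UBC,6,4,3,4,4.12
ABA,18S,7,6,6,6,6.24
ABA,CDC25,8,8,2,8,5.66
ABA,PP2A,9,9,1,9,5.20
ABA,GAPDH,10,10,10,10,10.00
Total,18S,1,4,4,4,2.83
Total,UBC,1,2,2,2,1.68
Total,CDC25,3,7,3,7,4.58
Total,PP2A,4,5,1,5,3.16
Total,Actin,5,1,5,1,2.24
Total,EF1-a,6,6,6,6,6.00
Total,TUA,7,3,7,3,4.58
Total,SAND,8,8,8,8,8.00
Total,GAPDH,9,9,10,9,9.24
Total,TUB,10,10,9,10,9.74
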