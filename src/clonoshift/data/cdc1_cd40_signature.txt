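# Anti-CD40 activated cDC1 gene signature (21 genes, mouse symbols),
# as defined in MC38 tumors; scored as the arithmetic mean of log-scale
# expression.
Relb
Etv3
Batf3
Aebp2
Nfkb2
Ccl22
Ccl5
Il15
Ccr7
Il15ra
Plxnc1
Pmp
Cd40
Birc2
Fscn1
Anxa3
Cacnb3
Nudt17
Socs2
Tspan3
Serpinb6b
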