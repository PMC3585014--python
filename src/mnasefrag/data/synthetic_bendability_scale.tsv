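# Synthetic strand-symmetric trinucleotide bendability scale (dimensionless).
# Constructed, not measured: value rises with G+C content (A+T-rich DNA is
# stiffer) plus a small deterministic per-pair offset to break degeneracy.
# Replace with a published 64-entry table via BendabilityScale.from_tsv().
# trinucleotide	bendability
AAA	-0.3380
AAC	-0.1544
AAG	-0.1402
AAT	-0.3742
ACA	-0.1494
ACC	0.0912
ACG	0.1548
ACT	-0.1724
AGA	-0.1254
AGC	0.0914
AGG	0.1267
AGT	-0.1724
ATA	-0.3228
ATC	-0.1284
ATG	-0.1503
ATT	-0.3742
CAA	-0.0891
CAC	0.1087
CAG	0.1028
CAT	-0.1503
CCA	0.1258
CCC	0.3604
CCG	0.3394
CCT	0.1267
CGA	0.1545
CGC	0.3860
CGG	0.3394
CGT	0.1548
CTA	-0.0664
CTC	0.1212
CTG	0.1028
CTT	-0.1402
GAA	-0.0921
GAC	0.1074
GAG	0.1212
GAT	-0.1284
GCA	0.1027
GCC	0.3907
GCG	0.3860
GCT	0.0914
GGA	0.1473
GGC	0.3907
GGG	0.3604
GGT	0.0912
GTA	-0.0680
GTC	0.1074
GTG	0.1087
GTT	-0.1544
TAA	-0.3464
TAC	-0.0680
TAG	-0.0664
TAT	-0.3228
TCA	-0.1183
TCC	0.1473
TCG	0.1545
TCT	-0.1254
TGA	-0.1183
TGC	0.1027
TGG	0.1258
TGT	-0.1494
TTA	-0.3464
TTC	-0.0921
TTG	-0.0891
TTT	-0.3380
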