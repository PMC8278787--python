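# synthetic demonstration trinucleotide rate table
# context-independent: transitions 1.5e-8, transversions 5e-9 per site per generation per haploid genome
# strand-closed by construction; illustrative only, not an empirical estimate
context	alt	mu
AAA	C	5.000000e-09
AAA	G	1.500000e-08
AAA	T	5.000000e-09
AAC	C	5.000000e-09
AAC	G	1.500000e-08
AAC	T	5.000000e-09
AAG	C	5.000000e-09
AAG	G	1.500000e-08
AAG	T	5.000000e-09
AAT	C	5.000000e-09
AAT	G	1.500000e-08
AAT	T	5.000000e-09
ACA	A	5.000000e-09
ACA	G	5.000000e-09
ACA	T	1.500000e-08
ACC	A	5.000000e-09
ACC	G	5.000000e-09
ACC	T	1.500000e-08
ACG	A	5.000000e-09
ACG	G	5.000000e-09
ACG	T	1.500000e-08
ACT	A	5.000000e-09
ACT	G	5.000000e-09
ACT	T	1.500000e-08
AGA	A	1.500000e-08
AGA	C	5.000000e-09
AGA	T	5.000000e-09
AGC	A	1.500000e-08
AGC	C	5.000000e-09
AGC	T	5.000000e-09
AGG	A	1.500000e-08
AGG	C	5.000000e-09
AGG	T	5.000000e-09
AGT	A	1.500000e-08
AGT	C	5.000000e-09
AGT	T	5.000000e-09
ATA	A	5.000000e-09
ATA	C	1.500000e-08
ATA	G	5.000000e-09
ATC	A	5.000000e-09
ATC	C	1.500000e-08
ATC	G	5.000000e-09
ATG	A	5.000000e-09
ATG	C	1.500000e-08
ATG	G	5.000000e-09
ATT	A	5.000000e-09
ATT	C	1.500000e-08
ATT	G	5.000000e-09
CAA	C	5.000000e-09
CAA	G	1.500000e-08
CAA	T	5.000000e-09
CAC	C	5.000000e-09
CAC	G	1.500000e-08
CAC	T	5.000000e-09
CAG	C	5.000000e-09
CAG	G	1.500000e-08
CAG	T	5.000000e-09
CAT	C	5.000000e-09
CAT	G	1.500000e-08
CAT	T	5.000000e-09
CCA	A	5.000000e-09
CCA	G	5.000000e-09
CCA	T	1.500000e-08
CCC	A	5.000000e-09
CCC	G	5.000000e-09
CCC	T	1.500000e-08
CCG	A	5.000000e-09
CCG	G	5.000000e-09
CCG	T	1.500000e-08
CCT	A	5.000000e-09
CCT	G	5.000000e-09
CCT	T	1.500000e-08
CGA	A	1.500000e-08
CGA	C	5.000000e-09
CGA	T	5.000000e-09
CGC	A	1.500000e-08
CGC	C	5.000000e-09
CGC	T	5.000000e-09
CGG	A	1.500000e-08
CGG	C	5.000000e-09
CGG	T	5.000000e-09
CGT	A	1.500000e-08
CGT	C	5.000000e-09
CGT	T	5.000000e-09
CTA	A	5.000000e-09
CTA	C	1.500000e-08
CTA	G	5.000000e-09
CTC	A	5.000000e-09
CTC	C	1.500000e-08
CTC	G	5.000000e-09
CTG	A	5.000000e-09
CTG	C	1.500000e-08
CTG	G	5.000000e-09
CTT	A	5.000000e-09
CTT	C	1.500000e-08
CTT	G	5.000000e-09
GAA	C	5.000000e-09
GAA	G	1.500000e-08
GAA	T	5.000000e-09
GAC	C	5.000000e-09
GAC	G	1.500000e-08
GAC	T	5.000000e-09
GAG	C	5.000000e-09
GAG	G	1.500000e-08
GAG	T	5.000000e-09
GAT	C	5.000000e-09
GAT	G	1.500000e-08
GAT	T	5.000000e-09
GCA	A	5.000000e-09
GCA	G	5.000000e-09
GCA	T	1.500000e-08
GCC	A	5.000000e-09
GCC	G	5.000000e-09
GCC	T	1.500000e-08
GCG	A	5.000000e-09
GCG	G	5.000000e-09
GCG	T	1.500000e-08
GCT	A	5.000000e-09
GCT	G	5.000000e-09
GCT	T	1.500000e-08
GGA	A	1.500000e-08
GGA	C	5.000000e-09
GGA	T	5.000000e-09
GGC	A	1.500000e-08
GGC	C	5.000000e-09
GGC	T	5.000000e-09
GGG	A	1.500000e-08
GGG	C	5.000000e-09
GGG	T	5.000000e-09
GGT	A	1.500000e-08
GGT	C	5.000000e-09
GGT	T	5.000000e-09
GTA	A	5.000000e-09
GTA	C	1.500000e-08
GTA	G	5.000000e-09
GTC	A	5.000000e-09
GTC	C	1.500000e-08
GTC	G	5.000000e-09
GTG	A	5.000000e-09
GTG	C	1.500000e-08
GTG	G	5.000000e-09
GTT	A	5.000000e-09
GTT	C	1.500000e-08
GTT	G	5.000000e-09
TAA	C	5.000000e-09
TAA	G	1.500000e-08
TAA	T	5.000000e-09
TAC	C	5.000000e-09
TAC	G	1.500000e-08
TAC	T	5.000000e-09
TAG	C	5.000000e-09
TAG	G	1.500000e-08
TAG	T	5.000000e-09
TAT	C	5.000000e-09
TAT	G	1.500000e-08
TAT	T	5.000000e-09
TCA	A	5.000000e-09
TCA	G	5.000000e-09
TCA	T	1.500000e-08
TCC	A	5.000000e-09
TCC	G	5.000000e-09
TCC	T	1.500000e-08
TCG	A	5.000000e-09
TCG	G	5.000000e-09
TCG	T	1.500000e-08
TCT	A	5.000000e-09
TCT	G	5.000000e-09
TCT	T	1.500000e-08
TGA	A	1.500000e-08
TGA	C	5.000000e-09
TGA	T	5.000000e-09
TGC	A	1.500000e-08
TGC	C	5.000000e-09
TGC	T	5.000000e-09
TGG	A	1.500000e-08
TGG	C	5.000000e-09
TGG	T	5.000000e-09
TGT	A	1.500000e-08
TGT	C	5.000000e-09
TGT	T	5.000000e-09
TTA	A	5.000000e-09
TTA	C	1.500000e-08
TTA	G	5.000000e-09
TTC	A	5.000000e-09
TTC	C	1.500000e-08
TTC	G	5.000000e-09
TTG	A	5.000000e-09
TTG	C	1.500000e-08
TTG	G	5.000000e-09
TTT	A	5.000000e-09
TTT	C	1.500000e-08
TTT	G	5.000000e-09
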