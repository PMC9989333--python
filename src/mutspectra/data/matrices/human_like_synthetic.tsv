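# SYNTHETIC hominid-like context matrix (constructed, not inferred from data):
# transitions 2.2x transversions, CpG transitions (NCG>NTG / CGN>CAN) 12x.
# Captures the qualitative structure of hominid context-specific rates for
# broad-scale experiments; relative rates, normalized at run time.
triplet	derived	rate
AAA	C	1.0
AAA	G	2.2
AAA	T	1.0
AAC	C	1.0
AAC	G	2.2
AAC	T	1.0
AAG	C	1.0
AAG	G	2.2
AAG	T	1.0
AAT	C	1.0
AAT	G	2.2
AAT	T	1.0
ACA	A	1.0
ACA	G	1.0
ACA	T	2.2
ACC	A	1.0
ACC	G	1.0
ACC	T	2.2
ACG	A	1.0
ACG	G	1.0
ACG	T	12.0
ACT	A	1.0
ACT	G	1.0
ACT	T	2.2
AGA	A	2.2
AGA	C	1.0
AGA	T	1.0
AGC	A	2.2
AGC	C	1.0
AGC	T	1.0
AGG	A	2.2
AGG	C	1.0
AGG	T	1.0
AGT	A	2.2
AGT	C	1.0
AGT	T	1.0
ATA	A	1.0
ATA	C	2.2
ATA	G	1.0
ATC	A	1.0
ATC	C	2.2
ATC	G	1.0
ATG	A	1.0
ATG	C	2.2
ATG	G	1.0
ATT	A	1.0
ATT	C	2.2
ATT	G	1.0
CAA	C	1.0
CAA	G	2.2
CAA	T	1.0
CAC	C	1.0
CAC	G	2.2
CAC	T	1.0
CAG	C	1.0
CAG	G	2.2
CAG	T	1.0
CAT	C	1.0
CAT	G	2.2
CAT	T	1.0
CCA	A	1.0
CCA	G	1.0
CCA	T	2.2
CCC	A	1.0
CCC	G	1.0
CCC	T	2.2
CCG	A	1.0
CCG	G	1.0
CCG	T	12.0
CCT	A	1.0
CCT	G	1.0
CCT	T	2.2
CGA	A	12.0
CGA	C	1.0
CGA	T	1.0
CGC	A	12.0
CGC	C	1.0
CGC	T	1.0
CGG	A	12.0
CGG	C	1.0
CGG	T	1.0
CGT	A	12.0
CGT	C	1.0
CGT	T	1.0
CTA	A	1.0
CTA	C	2.2
CTA	G	1.0
CTC	A	1.0
CTC	C	2.2
CTC	G	1.0
CTG	A	1.0
CTG	C	2.2
CTG	G	1.0
CTT	A	1.0
CTT	C	2.2
CTT	G	1.0
GAA	C	1.0
GAA	G	2.2
GAA	T	1.0
GAC	C	1.0
GAC	G	2.2
GAC	T	1.0
GAG	C	1.0
GAG	G	2.2
GAG	T	1.0
GAT	C	1.0
GAT	G	2.2
GAT	T	1.0
GCA	A	1.0
GCA	G	1.0
GCA	T	2.2
GCC	A	1.0
GCC	G	1.0
GCC	T	2.2
GCG	A	1.0
GCG	G	1.0
GCG	T	12.0
GCT	A	1.0
GCT	G	1.0
GCT	T	2.2
GGA	A	2.2
GGA	C	1.0
GGA	T	1.0
GGC	A	2.2
GGC	C	1.0
GGC	T	1.0
GGG	A	2.2
GGG	C	1.0
GGG	T	1.0
GGT	A	2.2
GGT	C	1.0
GGT	T	1.0
GTA	A	1.0
GTA	C	2.2
GTA	G	1.0
GTC	A	1.0
GTC	C	2.2
GTC	G	1.0
GTG	A	1.0
GTG	C	2.2
GTG	G	1.0
GTT	A	1.0
GTT	C	2.2
GTT	G	1.0
TAA	C	1.0
TAA	G	2.2
TAA	T	1.0
TAC	C	1.0
TAC	G	2.2
TAC	T	1.0
TAG	C	1.0
TAG	G	2.2
TAG	T	1.0
TAT	C	1.0
TAT	G	2.2
TAT	T	1.0
TCA	A	1.0
TCA	G	1.0
TCA	T	2.2
TCC	A	1.0
TCC	G	1.0
TCC	T	2.2
TCG	A	1.0
TCG	G	1.0
TCG	T	12.0
TCT	A	1.0
TCT	G	1.0
TCT	T	2.2
TGA	A	2.2
TGA	C	1.0
TGA	T	1.0
TGC	A	2.2
TGC	C	1.0
TGC	T	1.0
TGG	A	2.2
TGG	C	1.0
TGG	T	1.0
TGT	A	2.2
TGT	C	1.0
TGT	T	1.0
TTA	A	1.0
TTA	C	2.2
TTA	G	1.0
TTC	A	1.0
TTC	C	2.2
TTC	G	1.0
TTG	A	1.0
TTG	C	2.2
TTG	G	1.0
TTT	A	1.0
TTT	C	2.2
TTT	G	1.0
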