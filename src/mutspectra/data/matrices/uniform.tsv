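# Uniform (Jukes-Cantor) matrix: equal relative rate for all 192 mutation types.
# Rates are relative; normalize_overall_rate scales them to a target per-site rate.
triplet	derived	rate
AAA	C	1.0
AAA	G	1.0
AAA	T	1.0
AAC	C	1.0
AAC	G	1.0
AAC	T	1.0
AAG	C	1.0
AAG	G	1.0
AAG	T	1.0
AAT	C	1.0
AAT	G	1.0
AAT	T	1.0
ACA	A	1.0
ACA	G	1.0
ACA	T	1.0
ACC	A	1.0
ACC	G	1.0
ACC	T	1.0
ACG	A	1.0
ACG	G	1.0
ACG	T	1.0
ACT	A	1.0
ACT	G	1.0
ACT	T	1.0
AGA	A	1.0
AGA	C	1.0
AGA	T	1.0
AGC	A	1.0
AGC	C	1.0
AGC	T	1.0
AGG	A	1.0
AGG	C	1.0
AGG	T	1.0
AGT	A	1.0
AGT	C	1.0
AGT	T	1.0
ATA	A	1.0
ATA	C	1.0
ATA	G	1.0
ATC	A	1.0
ATC	C	1.0
ATC	G	1.0
ATG	A	1.0
ATG	C	1.0
ATG	G	1.0
ATT	A	1.0
ATT	C	1.0
ATT	G	1.0
CAA	C	1.0
CAA	G	1.0
CAA	T	1.0
CAC	C	1.0
CAC	G	1.0
CAC	T	1.0
CAG	C	1.0
CAG	G	1.0
CAG	T	1.0
CAT	C	1.0
CAT	G	1.0
CAT	T	1.0
CCA	A	1.0
CCA	G	1.0
CCA	T	1.0
CCC	A	1.0
CCC	G	1.0
CCC	T	1.0
CCG	A	1.0
CCG	G	1.0
CCG	T	1.0
CCT	A	1.0
CCT	G	1.0
CCT	T	1.0
CGA	A	1.0
CGA	C	1.0
CGA	T	1.0
CGC	A	1.0
CGC	C	1.0
CGC	T	1.0
CGG	A	1.0
CGG	C	1.0
CGG	T	1.0
CGT	A	1.0
CGT	C	1.0
CGT	T	1.0
CTA	A	1.0
CTA	C	1.0
CTA	G	1.0
CTC	A	1.0
CTC	C	1.0
CTC	G	1.0
CTG	A	1.0
CTG	C	1.0
CTG	G	1.0
CTT	A	1.0
CTT	C	1.0
CTT	G	1.0
GAA	C	1.0
GAA	G	1.0
GAA	T	1.0
GAC	C	1.0
GAC	G	1.0
GAC	T	1.0
GAG	C	1.0
GAG	G	1.0
GAG	T	1.0
GAT	C	1.0
GAT	G	1.0
GAT	T	1.0
GCA	A	1.0
GCA	G	1.0
GCA	T	1.0
GCC	A	1.0
GCC	G	1.0
GCC	T	1.0
GCG	A	1.0
GCG	G	1.0
GCG	T	1.0
GCT	A	1.0
GCT	G	1.0
GCT	T	1.0
GGA	A	1.0
GGA	C	1.0
GGA	T	1.0
GGC	A	1.0
GGC	C	1.0
GGC	T	1.0
GGG	A	1.0
GGG	C	1.0
GGG	T	1.0
GGT	A	1.0
GGT	C	1.0
GGT	T	1.0
GTA	A	1.0
GTA	C	1.0
GTA	G	1.0
GTC	A	1.0
GTC	C	1.0
GTC	G	1.0
GTG	A	1.0
GTG	C	1.0
GTG	G	1.0
GTT	A	1.0
GTT	C	1.0
GTT	G	1.0
TAA	C	1.0
TAA	G	1.0
TAA	T	1.0
TAC	C	1.0
TAC	G	1.0
TAC	T	1.0
TAG	C	1.0
TAG	G	1.0
TAG	T	1.0
TAT	C	1.0
TAT	G	1.0
TAT	T	1.0
TCA	A	1.0
TCA	G	1.0
TCA	T	1.0
TCC	A	1.0
TCC	G	1.0
TCC	T	1.0
TCG	A	1.0
TCG	G	1.0
TCG	T	1.0
TCT	A	1.0
TCT	G	1.0
TCT	T	1.0
TGA	A	1.0
TGA	C	1.0
TGA	T	1.0
TGC	A	1.0
TGC	C	1.0
TGC	T	1.0
TGG	A	1.0
TGG	C	1.0
TGG	T	1.0
TGT	A	1.0
TGT	C	1.0
TGT	T	1.0
TTA	A	1.0
TTA	C	1.0
TTA	G	1.0
TTC	A	1.0
TTC	C	1.0
TTC	G	1.0
TTG	A	1.0
TTG	C	1.0
TTG	G	1.0
TTT	A	1.0
TTT	C	1.0
TTT	G	1.0
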