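# Relative synonymous codon usage for a high-GC Streptomyces coelicolor-style
# genome (~72% GC). Fractions are per amino acid and sum to 1.
# columns: amino_acid <TAB> codon <TAB> fraction
amino_acid	codon	fraction
A	GCC	0.46
A	GCG	0.32
A	GCA	0.12
A	GCT	0.10
R	CGC	0.42
R	CGG	0.34
R	CGT	0.10
R	CGA	0.06
R	AGG	0.05
R	AGA	0.03
N	AAC	0.82
N	AAT	0.18
D	GAC	0.80
D	GAT	0.20
C	TGC	0.85
C	TGT	0.15
Q	CAG	0.84
Q	CAA	0.16
E	GAG	0.78
E	GAA	0.22
G	GGC	0.52
G	GGG	0.22
G	GGT	0.16
G	GGA	0.10
H	CAC	0.78
H	CAT	0.22
I	ATC	0.89
I	ATT	0.07
I	ATA	0.04
L	CTG	0.62
L	CTC	0.26
L	CTT	0.05
L	TTG	0.04
L	CTA	0.02
L	TTA	0.01
K	AAG	0.82
K	AAA	0.18
M	ATG	1.00
F	TTC	0.82
F	TTT	0.18
P	CCG	0.45
P	CCC	0.33
P	CCT	0.13
P	CCA	0.09
S	AGC	0.30
S	TCG	0.26
S	TCC	0.24
S	TCT	0.07
S	AGT	0.07
S	TCA	0.06
T	ACC	0.51
T	ACG	0.33
T	ACT	0.09
T	ACA	0.07
W	TGG	1.00
Y	TAC	0.80
Y	TAT	0.20
V	GTC	0.48
V	GTG	0.38
V	GTT	0.10
V	GTA	0.04
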