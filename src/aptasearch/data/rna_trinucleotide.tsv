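# aptasearch property table v1	unit=trinucleotide	alphabet=RNA
unit	stacking_energy	gc_content	purine_content
AAA	-0.930	0.0000	1.0000
AAC	-1.585	0.3333	0.6667
AAG	-1.505	0.3333	1.0000
AAU	-1.015	0.0000	0.6667
ACA	-2.175	0.3333	0.6667
ACC	-2.750	0.6667	0.3333
ACG	-2.300	0.6667	0.6667
ACU	-2.160	0.3333	0.3333
AGA	-2.215	0.3333	1.0000
AGC	-2.750	0.6667	0.6667
AGG	-2.670	0.6667	1.0000
AGU	-2.160	0.3333	0.6667
AUA	-1.215	0.0000	0.6667
AUC	-1.725	0.3333	0.3333
AUG	-1.605	0.3333	0.6667
AUU	-1.015	0.0000	0.3333
CAA	-1.520	0.3333	0.6667
CAC	-2.175	0.6667	0.3333
CAG	-2.095	0.6667	0.6667
CAU	-1.605	0.3333	0.3333
CCA	-2.685	0.6667	0.3333
CCC	-3.260	1.0000	0.0000
CCG	-2.810	1.0000	0.3333
CCU	-2.670	0.6667	0.0000
CGA	-2.355	0.6667	0.6667
CGC	-2.890	1.0000	0.3333
CGG	-2.810	1.0000	0.6667
CGU	-2.300	0.6667	0.3333
CUA	-1.705	0.3333	0.3333
CUC	-2.215	0.6667	0.0000
CUG	-2.095	0.6667	0.3333
CUU	-1.505	0.3333	0.0000
GAA	-1.640	0.3333	1.0000
GAC	-2.295	0.6667	0.6667
GAG	-2.215	0.6667	1.0000
GAU	-1.725	0.3333	0.6667
GCA	-2.765	0.6667	0.6667
GCC	-3.340	1.0000	0.3333
GCG	-2.890	1.0000	0.6667
GCU	-2.750	0.6667	0.3333
GGA	-2.805	0.6667	1.0000
GGC	-3.340	1.0000	0.6667
GGG	-3.260	1.0000	1.0000
GGU	-2.750	0.6667	0.6667
GUA	-1.785	0.3333	0.6667
GUC	-2.295	0.6667	0.3333
GUG	-2.175	0.6667	0.6667
GUU	-1.585	0.3333	0.3333
UAA	-1.130	0.0000	0.6667
UAC	-1.785	0.3333	0.3333
UAG	-1.705	0.3333	0.6667
UAU	-1.215	0.0000	0.3333
UCA	-2.230	0.3333	0.3333
UCC	-2.805	0.6667	0.0000
UCG	-2.355	0.6667	0.3333
UCU	-2.215	0.3333	0.0000
UGA	-2.230	0.3333	0.6667
UGC	-2.765	0.6667	0.3333
UGG	-2.685	0.6667	0.6667
UGU	-2.175	0.3333	0.3333
UUA	-1.130	0.0000	0.3333
UUC	-1.640	0.3333	0.0000
UUG	-1.520	0.3333	0.3333
UUU	-0.930	0.0000	0.0000
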