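# aptasearch group table v1	unit=residue	alphabet=protein
class_index	residues
0	AGV
1	ILFP
2	YMTS
3	HNQW
4	RK
5	DE
6	C
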