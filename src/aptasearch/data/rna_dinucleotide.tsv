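# aptasearch property table v1	unit=dinucleotide	alphabet=RNA
unit	stacking_energy	gc_content	purine_content
AA	-0.93	0.00	1.00
AC	-2.24	0.50	0.50
AG	-2.08	0.50	1.00
AU	-1.10	0.00	0.50
CA	-2.11	0.50	0.50
CC	-3.26	1.00	0.00
CG	-2.36	1.00	0.50
CU	-2.08	0.50	0.00
GA	-2.35	0.50	1.00
GC	-3.42	1.00	0.50
GG	-3.26	1.00	1.00
GU	-2.24	0.50	0.50
UA	-1.33	0.00	0.50
UC	-2.35	0.50	0.00
UG	-2.11	0.50	0.50
UU	-0.93	0.00	0.00
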