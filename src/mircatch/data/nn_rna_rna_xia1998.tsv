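# RNA:RNA Watson-Crick nearest-neighbor parameters (Xia et al. 1998,
# Biochemistry 37:14719).  Stacks keyed by the 5'->3' dinucleotide of one
# strand; 16 keys expanded from the 10 unique values by reverse-complement
# symmetry.  dH in kcal/mol, dS in cal/(mol*K).
# Initiation is one per-duplex term plus a penalty per terminal A:U pair.
stack	dH	dS
AA	-6.82	-19.0
AU	-9.38	-26.7
UA	-7.69	-20.5
CU	-10.48	-27.1
CA	-10.44	-26.9
GU	-11.40	-29.5
GA	-12.44	-32.5
CG	-10.64	-26.7
GG	-13.39	-32.7
GC	-14.88	-36.9
UU	-6.82	-19.0
UG	-10.44	-26.9
AC	-11.40	-29.5
AG	-10.48	-27.1
UC	-12.44	-32.5
CC	-13.39	-32.7
init	3.61	-1.5
terminal_AU	3.72	10.5
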