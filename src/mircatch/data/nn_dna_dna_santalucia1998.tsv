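# DNA:DNA nearest-neighbor parameters, unified set (SantaLucia 1998,
# PNAS 95:1460).  Stacks keyed by the 5'->3' dinucleotide of one strand;
# the 16 keys are expanded from the 10 unique values by reverse-complement
# symmetry.  dH in kcal/mol, dS in cal/(mol*K).
# Initiation is per duplex end, dependent on the terminal base pair.
stack	dH	dS
AA	-7.9	-22.2
AT	-7.2	-20.4
TA	-7.2	-21.3
CA	-8.5	-22.7
GT	-8.4	-22.4
CT	-7.8	-21.0
GA	-8.2	-22.2
CG	-10.6	-27.2
GC	-9.8	-24.4
GG	-8.0	-19.9
TT	-7.9	-22.2
TG	-8.5	-22.7
AC	-8.4	-22.4
AG	-7.8	-21.0
TC	-8.2	-22.2
CC	-8.0	-19.9
init_per_end_GC	0.1	-2.8
init_per_end_AT	2.3	4.1
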