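# Stacking free energies (dG37, kcal/mol) for adjacent base pairs in the
# simplified RNA folding model.  Row = (outer pair 5'X:Y3', inner pair).
# Watson-Crick/Watson-Crick stacks are dG37 values derived from the
# RNA:RNA nearest-neighbor set of Xia et al. 1998; stacks involving a
# G:U wobble are coarse placeholder values (-1.3 one wobble, -0.5 two
# wobbles) standing in for the full wobble tables, which this model
# deliberately does not resolve.
pair5	pair3	dG37
AU	AU	-0.93
AU	UA	-1.10
AU	CG	-2.25
AU	GC	-2.07
AU	GU	-1.30
AU	UG	-1.30
UA	AU	-1.33
UA	UA	-0.93
UA	CG	-2.36
UA	GC	-2.10
UA	GU	-1.30
UA	UG	-1.30
CG	AU	-2.10
CG	UA	-2.07
CG	CG	-3.25
CG	GC	-2.36
CG	GU	-1.30
CG	UG	-1.30
GC	AU	-2.36
GC	UA	-2.25
GC	CG	-3.44
GC	GC	-3.25
GC	GU	-1.30
GC	UG	-1.30
GU	AU	-1.30
GU	UA	-1.30
GU	CG	-1.30
GU	GC	-1.30
GU	GU	-0.50
GU	UG	-0.50
UG	AU	-1.30
UG	UA	-1.30
UG	CG	-1.30
UG	GC	-1.30
UG	GU	-0.50
UG	UG	-0.50
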