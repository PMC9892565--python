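# RNA Watson-Crick nearest-neighbour free energies, kcal/mol at 37 C,
# 1 M NaCl-equivalent (Turner-rule values; Xia et al. 1998 duplex set).
# stack keys are the top-strand dinucleotide 5'->3'; the bottom strand is
# its Watson-Crick complement read antiparallel.
# hairpin keys are loop sizes; loops > 9 extrapolate with 1.75*RT*ln(n/9).
kind	key	dg37
stack	AA	-0.93
stack	UU	-0.93
stack	AU	-1.10
stack	UA	-1.33
stack	CU	-2.08
stack	AG	-2.08
stack	CA	-2.11
stack	UG	-2.11
stack	GU	-2.24
stack	AC	-2.24
stack	GA	-2.35
stack	UC	-2.35
stack	CG	-2.36
stack	GG	-3.26
stack	CC	-3.26
stack	GC	-3.42
init	duplex	4.09
init	terminal_au	0.45
hairpin	3	5.4
hairpin	4	5.6
hairpin	5	5.7
hairpin	6	5.4
hairpin	7	6.0
hairpin	8	5.5
hairpin	9	6.4
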