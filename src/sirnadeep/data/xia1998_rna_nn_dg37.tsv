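# RNA/RNA Watson-Crick nearest-neighbor free energies, dG37 (kcal/mol).
# Values: Xia et al. (1998) Biochemistry 37:14719-14735, unified NN set.
# Steps are written 5'->3' on one strand of the duplex; symmetric pairs
# (e.g. CU/AG) carry the same published value on both orientations.
#init_dg=4.09
#terminal_au=0.45
step	dg_kcal_mol
AA	-0.93
UU	-0.93
AU	-1.10
UA	-1.33
CU	-2.08
AG	-2.08
CA	-2.11
UG	-2.11
GU	-2.24
AC	-2.24
GA	-2.35
UC	-2.35
CG	-2.36
GG	-3.26
CC	-3.26
GC	-3.42
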