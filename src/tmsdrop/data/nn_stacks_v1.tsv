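# Unified DNA nearest-neighbor stack free energies, dG37 in kcal/mol
# (SantaLucia 1998 unified parameter set; 10 unique stacks expanded to the
# 16 dinucleotide keys read 5'->3' on the top strand, paired with the
# Watson-Crick complement on the antiparallel bottom strand).
# INIT is the constant duplex-initiation penalty applied once per duplex.
AA	-1.00
AT	-0.88
AC	-1.44
AG	-1.28
TA	-0.58
TT	-1.00
TC	-1.30
TG	-1.45
CA	-1.45
CT	-1.28
CC	-1.84
CG	-2.17
GA	-1.30
GT	-1.44
GC	-2.24
GG	-1.84
INIT	1.96
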