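# Default dinucleotide twist table (EXTERNAL PROVENANCE).
# twist_deg: mean helical twist per dinucleotide step from the crystallographic
# compilation of B-DNA oligomer structures (Olson et al., PNAS 1998, Nucleic
# Acids Database survey).  stiffness: torsional stiffness per step in
# k_B*T/rad^2; shipped uniform at the sequence-averaged value 71.4 -- replace
# with step-resolved values if available.  This table is configuration, not a
# result: all package tests use uniform or synthetic tables.
step	twist_deg	stiffness
AA	35.1	71.4
AC	31.5	71.4
AG	31.9	71.4
AT	29.3	71.4
CA	37.3	71.4
CC	32.9	71.4
CG	36.1	71.4
CT	31.9	71.4
GA	36.3	71.4
GC	33.6	71.4
GG	32.9	71.4
GT	31.5	71.4
TA	37.8	71.4
TC	36.3	71.4
TG	37.3	71.4
TT	35.1	71.4
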