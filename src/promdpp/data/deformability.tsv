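# property_name: deformability
# step_size: 2
# units: dimensionless
# source: Olson et al. 1998 PNAS 95:11163, protein-induced deformability
AA	2.9
AC	2.3
AG	2.1
AT	1.6
CA	9.8
CC	6.1
CG	12.1
CT	2.1
GA	4.5
GC	4.0
GG	6.1
GT	2.3
TA	6.3
TC	4.5
TG	9.8
TT	2.9
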