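# property_name: zdna_as_energy
# step_size: 2
# units: kcal/mol
# source: SYNTHETIC STAND-IN: anti-syn Z-DNA stabilizing energies unavailable offline; values reflect published ordering (alternating pur-pyr steps favored, CG lowest)
AA	3.9
AC	3.3
AG	4.5
AT	5.9
CA	1.3
CC	4.0
CG	0.7
CT	4.5
GA	4.5
GC	4.0
GG	4.0
GT	3.3
TA	2.5
TC	4.5
TG	1.3
TT	3.9
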