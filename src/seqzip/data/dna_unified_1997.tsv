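# Unified DNA/DNA nearest-neighbor parameters (Allawi & SantaLucia 1997).
# stack	delta_H (kcal/mol)	delta_S (cal/mol/K)
AA	-7.9	-22.2
AC	-8.4	-22.4
AG	-7.8	-21.0
AT	-7.2	-20.4
CA	-8.5	-22.7
CC	-8.0	-19.9
CG	-10.6	-27.2
CT	-7.8	-21.0
GA	-8.2	-22.2
GC	-9.8	-24.4
GG	-8.0	-19.9
GT	-8.4	-22.4
TA	-7.2	-21.3
TC	-8.2	-22.2
TG	-8.5	-22.7
TT	-7.9	-22.2
init_AT	2.3	4.1
init_GC	0.1	-2.8
sym	0.0	-1.4
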