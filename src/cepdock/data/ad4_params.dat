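# Per-atom-type nonbonded parameters (AutoDock 4 style).
# Rii: sum of vdW radii of two like atoms (Å)
# epsii: vdW well depth (kcal/mol)
# vol: atomic solvation volume (Å^3)
# solpar: atomic solvation parameter
# hbond: D = donor hydrogen, A = acceptor heavy atom, - = neither
# atom_type  Rii    epsii   vol      solpar    hbond
H    2.00  0.020   0.0000   0.00051  -
HD   2.00  0.020   0.0000   0.00051  D
C    4.00  0.150  33.5103  -0.00143  -
A    4.00  0.150  33.5103  -0.00052  -
N    3.50  0.160  22.4493  -0.00162  -
NA   3.50  0.160  22.4493  -0.00162  A
OA   3.20  0.200  17.1573  -0.00251  A
SA   4.00  0.200  33.5103  -0.00214  A
S    4.00  0.200  33.5103  -0.00214  -
P    4.20  0.200  38.7924  -0.00110  -
F    3.09  0.080  15.4480  -0.00110  -
Cl   4.09  0.276  35.8235  -0.00110  -
Br   4.33  0.389  42.5661  -0.00110  -
I    4.72  0.550  55.0585  -0.00110  -
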