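# Bondi van der Waals radii, in Angstrom.
# Bondi, J. Phys. Chem. 68 (1964) 441, plus the commonly used group-14/15
# extensions. One "element radius" pair per line; '#' starts a comment.
H   1.20
He  1.40
B   1.92
C   1.70
N   1.55
O   1.52
F   1.47
Ne  1.54
Na  2.27
Mg  1.73
Al  1.84
Si  2.10
P   1.80
S   1.80
Cl  1.75
Ar  1.88
K   2.75
Ca  2.31
Ga  1.87
Ge  2.11
As  1.85
Se  1.90
Br  1.85
Kr  2.02
In  1.93
Sn  2.17
Sb  2.06
Te  2.06
I   1.98
Xe  2.16
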