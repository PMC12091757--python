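# UFF nonbonded Lennard-Jones parameters (Rappe, Casewit, Colwell,
# Goddard, Skiff, J. Am. Chem. Soc. 114 (1992) 10024), version 1.
#
# sigma is the UFF van der Waals distance x_i (location of the potential
# minimum, Angstrom); epsilon is the well depth D_i (kcal/mol).
# mass is the IUPAC 2021 standard atomic weight (amu).
#
# element  epsilon(kcal/mol)  sigma(A)  mass(amu)
H    0.044   2.886    1.008
C    0.105   3.851   12.011
N    0.069   3.660   14.007
O    0.060   3.500   15.999
F    0.050   3.364   18.998
P    0.305   4.147   30.974
S    0.274   4.035   32.060
Cl   0.227   3.947   35.450
Br   0.251   4.189   79.904
I    0.339   4.500  126.904
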