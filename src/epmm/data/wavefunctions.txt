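# epmm wavefunction table, format version 1
#
# Per-shell single-zeta Slater-type atomic orbitals with Clementi-Raimondi
# effective exponents.  Spherically averaged shell densities are
#   rho(r) = occ * N^2 r^(2n-2) exp(-2 zeta r) / (4 pi),  N^2 = (2 zeta)^(2n+1)/(2n)!
# (Bohr units).  Core/valence split follows the noble-gas core convention.
#
# ELEMENT <symbol> <Z>
# SHELL <label> <n> <zeta/Bohr^-1> <occupation> <core|valence>

ELEMENT H 1
SHELL 1s 1 1.0000 1 valence

ELEMENT C 6
SHELL 1s 1 5.6727 2 core
SHELL 2s 2 1.6083 2 valence
SHELL 2p 2 1.5679 2 valence

ELEMENT N 7
SHELL 1s 1 6.6651 2 core
SHELL 2s 2 1.9237 2 valence
SHELL 2p 2 1.9170 3 valence

ELEMENT O 8
SHELL 1s 1 7.6579 2 core
SHELL 2s 2 2.2458 2 valence
SHELL 2p 2 2.2266 4 valence

ELEMENT Mg 12
SHELL 1s 1 11.6089 2 core
SHELL 2s 2 3.6960 2 core
SHELL 2p 2 4.1734 6 core
SHELL 3s 3 1.1025 2 valence

ELEMENT P 15
SHELL 1s 1 14.5578 2 core
SHELL 2s 2 5.3757 2 core
SHELL 2p 2 5.9885 6 core
SHELL 3s 3 1.8806 2 valence
SHELL 3p 3 1.6288 3 valence

ELEMENT S 16
SHELL 1s 1 15.5409 2 core
SHELL 2s 2 5.7710 2 core
SHELL 2p 2 6.3669 6 core
SHELL 3s 3 2.1223 2 valence
SHELL 3p 3 1.8273 4 valence
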