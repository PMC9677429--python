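EPMM-DATABANK 1
# Fixture pseudoatom databank covering H, C, N, O, P, S, Mg and water.
# Parameters are synthetic but physically sane (kappa in (0.5, 2), valence
# populations near neutral-atom values); they make no claim of numerical
# agreement with any production databank.  Deformation radial exponents:
# second-row atoms n(l) = 2,2,3,4; P n(l) = 2,4,6,8; S n(l) = 6,6,6,6.
# Deformation zeta values are density-scale (twice the orbital exponent).

ENTRY H_on_O
KEY H O
PARAM P_core 0.0 P_val 0.840000 kappa 1.1600 kappa_prime 1.1800
RADIAL zeta 2.6000 n 0 1 2 3 4
PLM 1 0 0.080000
FRAME auto
PROVENANCE fixture: hydroxyl/water hydrogen
END

ENTRY H_on_N
KEY H N
PARAM P_core 0.0 P_val 0.800000 kappa 1.1800 kappa_prime 1.2000
RADIAL zeta 2.6000 n 0 1 2 3 4
PLM 1 0 0.080000
FRAME auto
PROVENANCE fixture: amine/ammonium hydrogen
END

ENTRY H_on_C
KEY H C
PARAM P_core 0.0 P_val 0.950000 kappa 1.1200 kappa_prime 1.1500
RADIAL zeta 2.6000 n 0 1 2 3 4
PLM 1 0 0.100000
FRAME auto
PROVENANCE fixture: aliphatic hydrogen
END

ENTRY H_generic
KEY H *
PARAM P_core 0.0 P_val 0.900000 kappa 1.1500 kappa_prime 1.1500
RADIAL zeta 2.6000 n 0 1 2 3 4
FRAME auto
PROVENANCE fixture: fallback hydrogen (spherical)
END

ENTRY C_carboxyl
KEY C C O O
PARAM P_core 2.0 P_val 3.700000 kappa 1.0300 kappa_prime 0.9800
RADIAL zeta 3.1358 n 2 2 2 3 4
PLM 2 0 -0.150000
FRAME auto
PROVENANCE fixture: carboxylate carbon
END

ENTRY C_generic
KEY C *
PARAM P_core 2.0 P_val 4.000000 kappa 1.0100 kappa_prime 0.9900
RADIAL zeta 3.1358 n 2 2 2 3 4
PLM 1 0 0.080000
FRAME auto
PROVENANCE fixture: fallback carbon
END

ENTRY N_ammonium
KEY N C H H H
PARAM P_core 2.0 P_val 4.600000 kappa 1.0500 kappa_prime 1.0200
RADIAL zeta 3.8340 n 2 2 2 3 4
PLM 1 0 0.100000
FRAME auto
PROVENANCE fixture: protonated amine nitrogen
END

ENTRY N_generic
KEY N *
PARAM P_core 2.0 P_val 5.050000 kappa 1.0000 kappa_prime 1.0000
RADIAL zeta 3.8340 n 2 2 2 3 4
PLM 1 0 0.100000
PLM 2 0 -0.080000
FRAME auto
PROVENANCE fixture: fallback nitrogen
END

ENTRY O_water
KEY O H H
PARAM P_core 2.0 P_val 6.320000 kappa 0.9750 kappa_prime 1.1000
RADIAL zeta 4.4532 n 2 2 2 3 4
PLM 1 0 0.080000
PLM 2 0 -0.060000
FRAME auto
PROVENANCE fixture: water oxygen
END

ENTRY O_hydroxyl
KEY O C H
PARAM P_core 2.0 P_val 6.300000 kappa 0.9800 kappa_prime 1.0800
RADIAL zeta 4.4532 n 2 2 2 3 4
PLM 1 0 0.070000
FRAME auto
PROVENANCE fixture: hydroxyl oxygen
END

ENTRY O_carbonyl
KEY O C
PARAM P_core 2.0 P_val 6.250000 kappa 0.9800 kappa_prime 1.0800
RADIAL zeta 4.4532 n 2 2 2 3 4
PLM 1 0 0.100000
PLM 2 0 -0.080000
FRAME auto
PROVENANCE fixture: carbonyl/carboxylate oxygen
END

ENTRY O_phosphate_terminal
KEY O P
PARAM P_core 2.0 P_val 6.450000 kappa 0.9650 kappa_prime 1.0500
RADIAL zeta 4.4532 n 2 2 2 3 4
PLM 1 0 0.090000
FRAME auto
PROVENANCE fixture: terminal phosphate oxygen
END

ENTRY O_phosphate_bridge
KEY O P P
PARAM P_core 2.0 P_val 6.150000 kappa 0.9850 kappa_prime 1.0500
RADIAL zeta 4.4532 n 2 2 2 3 4
PLM 1 0 0.060000
FRAME auto
PROVENANCE fixture: P-O-P bridging oxygen
END

ENTRY O_phosphate_ester
KEY O C P
PARAM P_core 2.0 P_val 6.200000 kappa 0.9850 kappa_prime 1.0500
RADIAL zeta 4.4532 n 2 2 2 3 4
PLM 1 0 0.060000
FRAME auto
PROVENANCE fixture: phosphoester oxygen
END

ENTRY O_generic
KEY O *
PARAM P_core 2.0 P_val 6.200000 kappa 0.9800 kappa_prime 1.0800
RADIAL zeta 4.4532 n 2 2 2 3 4
FRAME auto
PROVENANCE fixture: fallback oxygen (spherical)
END

ENTRY P_generic
KEY P *
PARAM P_core 10.0 P_val 4.400000 kappa 1.0500 kappa_prime 1.0000
RADIAL zeta 3.2576 n 2 2 4 6 8
PLM 3 0 0.050000
FRAME auto
PROVENANCE fixture: phosphate phosphorus; n(l=1..4) = 2,4,6,8
END

ENTRY S_generic
KEY S *
PARAM P_core 10.0 P_val 5.900000 kappa 1.0200 kappa_prime 1.0000
RADIAL zeta 3.6546 n 6 6 6 6 6
PLM 1 0 0.050000
FRAME auto
PROVENANCE fixture: sulfur; n(l=1..4) = 6,6,6,6
END

ENTRY Mg_cation
KEY Mg *
PARAM P_core 10.0 P_val 0.300000 kappa 1.3000 kappa_prime 1.0000
RADIAL zeta 2.2050 n 2 2 3 4 4
FRAME auto
PROVENANCE fixture: near-spherical magnesium cation
END
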