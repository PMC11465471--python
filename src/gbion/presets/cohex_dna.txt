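# Pair-class coefficients optimized for trivalent cobalt hexammine
# (CoHex3+) around B-DNA. Near-zero K_GB pushes solute-cation and
# ion-ion electrostatics to the Coulomb-in-water limit.
gi_coef_1_p 0.01
gi_coef_1_n 0.01
gi_coef_1_pp 0.06
gi_coef_1_pn 0.06
gi_coef_1_nn 0.06
intdiel_ion_1_p 1
intdiel_ion_1_n 1
intdiel_ion_1_pp 2
intdiel_ion_1_pn 2
intdiel_ion_1_nn 2
extdiel 78.5
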