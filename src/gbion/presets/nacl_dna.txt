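# Pair-class coefficients optimized for Na+/Cl- around B-DNA.
# gi_coef (K_GB) scales the canonical exponent: gamma = 4*K_GB.
# intdiel_ion (K_eps) is the pair internal dielectric eps_in.
gi_coef_1_p 1
gi_coef_1_n 0.05
gi_coef_1_pp 1
gi_coef_1_pn 0.05
gi_coef_1_nn 1
intdiel_ion_1_p 54
intdiel_ion_1_n 8
intdiel_ion_1_pp 54
intdiel_ion_1_pn 8
intdiel_ion_1_nn 8
extdiel 78.5
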