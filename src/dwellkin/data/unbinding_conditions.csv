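# Published unbinding-side rate constants for the 8-repeat array under
# different DNA sequences / salt conditions. Units: s^-1.
condition,km2,k3,km3
homopolymeric_KCl,0.66,0.36,0.222
t_anchored_KCl,0.48,0.06,0.31
homopolymeric_MgCl2,1.28,0.32,1.40
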