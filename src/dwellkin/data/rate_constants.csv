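# Published microscopic rate constants for 8-, 12- and 16-repeat arrays
# binding homopolymeric duplex DNA. Units: k2 in nM^-1 s^-1, all others s^-1.
construct,k1,km1,k2,km2,k3,km3
array8,0.17,0.13,1.1,0.66,0.36,0.222
array12,0.135,1.26,0.31,0.130,0.043,0.0435
array16,0.26,0.43,0.39,0.299,0.074,0.078
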