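>tRNA-iMet
GCTCTGATACCA
>tRNA-Lys_synthetic
CTCCCTTAGCCA
>tRNA-Trp_synthetic
GACCGGTTAGCA
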