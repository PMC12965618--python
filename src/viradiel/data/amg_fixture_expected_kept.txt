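g01
g08
g09
g11
g12
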