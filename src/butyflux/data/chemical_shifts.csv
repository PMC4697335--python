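compound,position,shift_ppm
lysine,6,41.75
lysine,2,57.19
butyrate,2,42.33
butyrate,4,15.95
acetate,2,25.99
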