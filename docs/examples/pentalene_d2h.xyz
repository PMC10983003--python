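8
pentalene_d2h_1.4
C   0.00000000 0.70000000 0.00000000
C   0.00000000 -0.70000000 0.00000000
C   -1.33147912 1.13262379 0.00000000
C   -2.15437848 0.00000000 0.00000000
C   -1.33147912 -1.13262379 0.00000000
C   1.33147912 1.13262379 0.00000000
C   2.15437848 0.00000000 0.00000000
C   1.33147912 -1.13262379 0.00000000
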