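6
C6_ring_1.397
C   1.39700000 0.00000000 0.00000000
C   0.69850000 1.20983749 0.00000000
C   -0.69850000 1.20983749 0.00000000
C   -1.39700000 0.00000000 0.00000000
C   -0.69850000 -1.20983749 0.00000000
C   0.69850000 -1.20983749 0.00000000
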