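4
C4_ring_1.4
C   0.98994949 0.00000000 0.00000000
C   0.00000000 0.98994949 0.00000000
C   -0.98994949 0.00000000 0.00000000
C   -0.00000000 -0.98994949 0.00000000
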