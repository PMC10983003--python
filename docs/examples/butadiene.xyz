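4
polyene_4
C   0.00000000 0.00000000 0.00000000
C   1.21243557 0.70000000 0.00000000
C   2.42487113 0.00000000 0.00000000
C   3.63730670 0.70000000 0.00000000
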