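MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF PLANTED_SYNTH
letter-probability matrix: alength= 4 w= 19 nsites= 20 E= 0
0.026667 0.026667 0.026667 0.920000
0.026667 0.920000 0.026667 0.026667
0.026667 0.026667 0.920000 0.026667
0.920000 0.026667 0.026667 0.026667
0.460000 0.040000 0.460000 0.040000
0.026667 0.026667 0.026667 0.920000
0.920000 0.026667 0.026667 0.026667
0.026667 0.026667 0.920000 0.026667
0.026667 0.920000 0.026667 0.026667
0.026667 0.920000 0.026667 0.026667
0.920000 0.026667 0.026667 0.026667
0.026667 0.920000 0.026667 0.026667
0.026667 0.920000 0.026667 0.026667
0.040000 0.460000 0.040000 0.460000
0.026667 0.026667 0.920000 0.026667
0.026667 0.026667 0.920000 0.026667
0.026667 0.026667 0.026667 0.920000
0.026667 0.026667 0.920000 0.026667
0.920000 0.026667 0.026667 0.026667

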