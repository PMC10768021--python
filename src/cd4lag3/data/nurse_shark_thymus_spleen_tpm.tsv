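gene	spleen	thymus
CD4	1.10	6.01
LAG-3	0.43	0.39
CD8A	18.49	470.56
CD8B	6.73	190.14
LCK	18.75	171.45
CD3Z	104.18	812.26
TCRA	114.51	480.93
TCRB	44.46	533.84
PAX5	3.61	0.04
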