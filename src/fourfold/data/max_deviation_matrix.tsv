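nt	A	T	G	C
A	0.8882	0.0013	0.0000	0.1104
T	0.0008	0.9882	0.0007	0.0103
G	0.1729	0.1549	0.5864	0.0858
C	0.1719	0.0025	0.2884	0.5372
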