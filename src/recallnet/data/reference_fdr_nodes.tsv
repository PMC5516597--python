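node	r	p	ci
Left fusiform	0.115	0.003	0.04,0.19
Left superiortemporal	0.149	0.000112	0.08,0.22
Left temporalpole	0.121	0.0018	0.04,0.20
Left transversetemporal	0.124	0.0013	0.05,0.20
Left insula	0.117	0.0025	0.04,0.19
Right fusiform	0.14	0.000286	0.07,0.22
Right inferiortemporal	0.143	0.000215	0.07,0.22
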