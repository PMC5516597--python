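node_a	node_b	r	p
Left fusiform	Left superiortemporal	0.13	0.000795
Left fusiform	Left temporalpole	0.114	0.0033
Left fusiform	Left middletemporal	0.107	0.0057
Left insula	Left pericalcarine	0.133	0.000576
Left insula	Left lateraloccipital	0.121	0.0018
Left insula	Left accumbens-area	0.12	0.002
Left superiortemporal	Left lingual	0.189	8.87e-07
Left superiortemporal	Left pericalcarine	0.145	0.000179
Left superiortemporal	Left accumbens-area	0.139	0.000321
Left superiortemporal	Left insula	0.132	0.00063
Left superiortemporal	Left lateraloccipital	0.13	0.000809
Left superiortemporal	Left lateralorbitofrontal	0.123	0.0015
Left superiortemporal	Left hippocampus	0.119	0.0021
Left superiortemporal	Left caudate	0.105	0.0066
Left temporalpole	Left lingual	0.145	0.00017
Left temporalpole	Left accumbens-area	0.134	0.00056
Left temporalpole	Left pericalcarine	0.122	0.0016
Left temporalpole	Left caudate	0.112	0.0039
Right fusiform	Right accumbens-area	0.116	0.0027
Right fusiform	Right inferiortemporal	0.115	0.003
Right inferiortemporal	Right superiortemporal	0.114	0.0032
Right inferiortemporal	Right accumbens-area	0.106	0.0063
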