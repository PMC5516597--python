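metric	r	p
network_cost	0.102	0.0086
global_efficiency_ci	0.013	0.73
clustering_ci	-0.025	0.53
char_path_length_ci	0.057	0.14
betweenness_ci	0.013	0.73
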