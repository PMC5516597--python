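node	r_degree	p_degree	r_volume	p_volume
Left superiortemporal	0.149	0.000112	0.008	0.844
Right inferiortemporal	0.143	0.000215	0.011	0.775
Right fusiform	0.14	0.000286	0.007	0.854
Left transversetemporal	0.124	0.00133	0.027	0.488
Left temporalpole	0.121	0.0018	0.033	0.402
Left insula	0.117	0.00245	0.059	0.13
Left fusiform	0.115	0.00298	0.007	0.852
Right temporalpole	0.113	0.00346	0.016	0.685
Left Accumbens area	0.103	0.00788	0.008	0.828
Right parahippocampal	0.09	0.0198	0.067	0.0825
Right insula	0.088	0.023	0.046	0.239
Right Hippocampus	0.087	0.0243	0.03	0.438
Left isthmuscingulate	0.083	0.0315	0.02	0.605
Right transversetemporal	0.081	0.0372	0.069	0.0759
Right Putamen	0.08	0.0396	0.047	0.224
Right lateraloccipital	0.078	0.0456	0.016	0.681
Right superiortemporal	0.077	0.0474	0.001	0.983
Right precentral	0.075	0.0529	0.016	0.687
Left supramarginal	0.075	0.0534	0.014	0.725
Left bankssts	0.073	0.0607	0.054	0.167
Left Thalamus Proper	0.072	0.0624	0.032	0.411
Right inferiorparietal	0.072	0.063	0.019	0.634
Left lateralorbitofrontal	0.071	0.0682	0.043	0.265
Right postcentral	0.069	0.075	0.042	0.285
Right Accumbens area	0.066	0.0895	0.032	0.404
Left caudalanteriorcingulate	0.066	0.0917	0.014	0.723
Right Amygdala	0.065	0.0923	0.011	0.775
Left precuneus	0.065	0.0947	0.04	0.309
Right bankssts	0.064	0.0975	0.04	0.305
Right Caudate	0.064	0.101	0.029	0.455
Left Hippocampus	0.063	0.107	0.016	0.688
Left entorhinal	0.062	0.108	0.102	0.00865
Right caudalmiddlefrontal	0.061	0.115	0.078	0.0433
Left middletemporal	0.06	0.123	0.043	0.266
Left inferiorparietal	0.059	0.127	0.017	0.66
Right entorhinal	0.057	0.143	0.07	0.0718
Left Pallidum	0.053	0.172	0.02	0.599
Left posteriorcingulate	0.05	0.195	0.012	0.755
Right rostralmiddlefrontal	0.05	0.2	0.013	0.742
Right posteriorcingulate	0.049	0.21	0.01	0.797
Left Putamen	0.044	0.256	0.037	0.344
Left lingual	0.043	0.266	0.052	0.178
Left parahippocampal	0.039	0.316	0.002	0.969
Right precuneus	0.039	0.317	0.043	0.265
Right superiorparietal	0.038	0.328	0.007	0.864
Right middletemporal	0.038	0.33	0.051	0.187
Right caudalanteriorcingulate	0.037	0.34	0.053	0.175
Right paracentral	0.036	0.355	0.041	0.295
Right isthmuscingulate	0.033	0.398	0.044	0.263
Left precentral	0.033	0.4	0.079	0.0414
Right parsorbitalis	0.032	0.415	0.029	0.45
Left postcentral	0.03	0.44	0.025	0.517
Left parstriangularis	0.03	0.444	0.045	0.249
Left inferiortemporal	0.028	0.468	0.036	0.356
Right lateralorbitofrontal	0.027	0.48	0.036	0.358
Left paracentral	0.026	0.503	0.028	0.464
Left parsorbitalis	0.025	0.525	0.026	0.5
Right medialorbitofrontal	0.024	0.544	0.007	0.863
Left lateraloccipital	0.023	0.547	0.018	0.641
Left medialorbitofrontal	0.022	0.577	0.013	0.729
Right Thalamus Proper	0.02	0.607	0.049	0.211
Left Amygdala	0.02	0.609	0.062	0.109
Left Caudate	0.019	0.626	0.024	0.541
Left pericalcarine	0.017	0.659	0.066	0.0893
Right supramarginal	0.017	0.662	0.041	0.296
Right cuneus	0.016	0.682	0.036	0.357
Left rostralanteriorcingulate	0.015	0.705	0.021	0.593
Left parsopercularis	0.014	0.718	0.008	0.839
Right lingual	0.013	0.739	0.069	0.0736
Left caudalmiddlefrontal	0.012	0.759	0.02	0.601
Left rostralmiddlefrontal	0.011	0.786	0.015	0.699
Right parstriangularis	0.01	0.799	0.006	0.876
Right Pallidum	0.009	0.807	0.017	0.657
Left superiorfrontal	0.009	0.814	0.059	0.127
Right parsopercularis	0.008	0.83	0.032	0.406
Left superiorparietal	0.008	0.844	0.02	0.61
Left frontalpole	0.007	0.855	0.027	0.492
Right superiorfrontal	0.007	0.865	0.087	0.0246
Right frontalpole	0.006	0.885	0.023	0.547
Left cuneus	0.005	0.906	0.094	0.015
Right pericalcarine	0.001	0.981	0.05	0.2
Right rostralanteriorcingulate	0.0	0.999	0.0	0.994
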