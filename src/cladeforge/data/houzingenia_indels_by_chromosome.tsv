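chrom	n_indels	length_mb	mean_size_nt	max_size_nt
Chr01	63848	55.9	6.3	187
Chr02	60823	62.8	5.9	230
Chr03	48607	45.8	6.1	262
Chr04	58550	62.2	6.0	182
Chr05	49943	64.1	5.7	164
Chr06	58156	51.1	6.5	173
Chr07	67740	61.0	6.4	270
Chr08	67069	57.1	6.5	188
Chr09	72303	70.7	6.7	183
Chr10	59521	62.2	6.0	214
Chr11	62707	62.7	6.1	220
Chr12	40747	35.4	6.0	181
Chr13	51732	58.3	6.0	197
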