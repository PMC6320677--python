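partition	n_recipient	n_control
genome	188472	182563
Chr01	12808	12808
Chr02	17118	17094
Chr03	11956	11353
Chr04	17292	16643
Chr05	18950	18065
Chr06	11013	10732
Chr07	15822	14649
Chr08	12904	12911
Chr09	15131	14922
Chr10	17585	16895
Chr11	15741	14941
Chr12	8600	8636
Chr13	13552	12914
genic	7843	7419
genes_hit	4808	4721
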