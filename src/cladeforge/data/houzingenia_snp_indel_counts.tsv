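species	accession	n_snps	n_indels
G_raimondii	D5-8	7909366	451713
G_armourianum	D2-1-6	7525371	442985
G_harknessii	D2-2	8140633	474421
G_turneri	D10-7	8155064	475161
G_aridum	D4-185	8555662	487561
G_lobatum	D7-157	8651866	490322
G_laxum	D9-4	8015127	462728
G_schwendimanii	D11-1	8606096	491961
G_thurberi	D1-35	8139420	478238
G_trilobum	D8-8	8232774	482728
G_davidsonii	D3D-27	8539202	493939
G_klotzschianum	D3K-57	8545127	494072
G_gossypioides	D6-5	8359287	513538
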