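species	accession	total_length_mb	genome_size_mb
G_raimondii	D5-8	592.04	880
G_armourianum	D2-1-6	671.70	856
G_harknessii	JFW	643.05	910
G_turneri	D10-7	774.62	910
G_aridum	DRD-185	648.51	919
G_lobatum	D7-157	654.85	934
G_laxum	D9-4	720.31	934
G_schwendimanii	D11-1	651.41	929
G_thurberi	D1-35	605.21	841
G_trilobum	D8-8	586.05	851
G_davidsonii	D3D-27	629.89	910
G_klotzschianum	D3K-57	596.12	880
G_gossypioides	D6-5	585.41	841
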