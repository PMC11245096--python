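class	total_genomes	soil	engineered	freshwater	host-associated	marine	non-marine saline and alkaline	terrestrial non-soil
Blastocatellia	215	64	103	35	8	1	0	4
Terriglobia	1006	537	179	197	50	16	0	27
Thermoanaerobaculia	153	25	49	22	37	17	0	3
Vicinamibacteria	231	44	35	59	47	46	0	0
Aminicenantia	119	7	27	49	0	35	1	0
Holophagae	206	16	30	151	4	5	0	0
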