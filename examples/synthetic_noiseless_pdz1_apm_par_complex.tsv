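experiment_id	replicate_id	ligand_total_molar	intensity	is_control
pdz1-apm+par-complex	r1	0	4000	True
pdz1-apm+par-complex	r1	0.0001	6.5712610253005899	False
pdz1-apm+par-complex	r1	5.0000000000000002e-05	13.134006205668847	False
pdz1-apm+par-complex	r1	2.5000000000000001e-05	26.233758254047057	False
pdz1-apm+par-complex	r1	1.2500000000000001e-05	52.328999540833365	False
pdz1-apm+par-complex	r1	6.2500000000000003e-06	104.09234492950192	False
pdz1-apm+par-complex	r1	3.1250000000000001e-06	205.83609306757867	False
pdz1-apm+par-complex	r1	1.5625000000000001e-06	401.69725528366882	False
pdz1-apm+par-complex	r1	7.8125000000000004e-07	760.48179117311099	False
pdz1-apm+par-complex	r1	3.9062500000000002e-07	1345.6371212478721	False
pdz1-apm+par-complex	r1	1.9531250000000001e-07	2105.2904783482368	False
pdz1-apm+par-complex	r2	0	4000	True
pdz1-apm+par-complex	r2	0.0001	6.5712610253005899	False
pdz1-apm+par-complex	r2	5.0000000000000002e-05	13.134006205668847	False
pdz1-apm+par-complex	r2	2.5000000000000001e-05	26.233758254047057	False
pdz1-apm+par-complex	r2	1.2500000000000001e-05	52.328999540833365	False
pdz1-apm+par-complex	r2	6.2500000000000003e-06	104.09234492950192	False
pdz1-apm+par-complex	r2	3.1250000000000001e-06	205.83609306757867	False
pdz1-apm+par-complex	r2	1.5625000000000001e-06	401.69725528366882	False
pdz1-apm+par-complex	r2	7.8125000000000004e-07	760.48179117311099	False
pdz1-apm+par-complex	r2	3.9062500000000002e-07	1345.6371212478721	False
pdz1-apm+par-complex	r2	1.9531250000000001e-07	2105.2904783482368	False
pdz1-apm+par-complex	r3	0	4000	True
pdz1-apm+par-complex	r3	0.0001	6.5712610253005899	False
pdz1-apm+par-complex	r3	5.0000000000000002e-05	13.134006205668847	False
pdz1-apm+par-complex	r3	2.5000000000000001e-05	26.233758254047057	False
pdz1-apm+par-complex	r3	1.2500000000000001e-05	52.328999540833365	False
pdz1-apm+par-complex	r3	6.2500000000000003e-06	104.09234492950192	False
pdz1-apm+par-complex	r3	3.1250000000000001e-06	205.83609306757867	False
pdz1-apm+par-complex	r3	1.5625000000000001e-06	401.69725528366882	False
pdz1-apm+par-complex	r3	7.8125000000000004e-07	760.48179117311099	False
pdz1-apm+par-complex	r3	3.9062500000000002e-07	1345.6371212478721	False
pdz1-apm+par-complex	r3	1.9531250000000001e-07	2105.2904783482368	False
pdz1-apm+par-complex	r4	0	4000	True
pdz1-apm+par-complex	r4	0.0001	6.5712610253005899	False
pdz1-apm+par-complex	r4	5.0000000000000002e-05	13.134006205668847	False
pdz1-apm+par-complex	r4	2.5000000000000001e-05	26.233758254047057	False
pdz1-apm+par-complex	r4	1.2500000000000001e-05	52.328999540833365	False
pdz1-apm+par-complex	r4	6.2500000000000003e-06	104.09234492950192	False
pdz1-apm+par-complex	r4	3.1250000000000001e-06	205.83609306757867	False
pdz1-apm+par-complex	r4	1.5625000000000001e-06	401.69725528366882	False
pdz1-apm+par-complex	r4	7.8125000000000004e-07	760.48179117311099	False
pdz1-apm+par-complex	r4	3.9062500000000002e-07	1345.6371212478721	False
pdz1-apm+par-complex	r4	1.9531250000000001e-07	2105.2904783482368	False
pdz1-apm+par-complex	r5	0	4000	True
pdz1-apm+par-complex	r5	0.0001	6.5712610253005899	False
pdz1-apm+par-complex	r5	5.0000000000000002e-05	13.134006205668847	False
pdz1-apm+par-complex	r5	2.5000000000000001e-05	26.233758254047057	False
pdz1-apm+par-complex	r5	1.2500000000000001e-05	52.328999540833365	False
pdz1-apm+par-complex	r5	6.2500000000000003e-06	104.09234492950192	False
pdz1-apm+par-complex	r5	3.1250000000000001e-06	205.83609306757867	False
pdz1-apm+par-complex	r5	1.5625000000000001e-06	401.69725528366882	False
pdz1-apm+par-complex	r5	7.8125000000000004e-07	760.48179117311099	False
pdz1-apm+par-complex	r5	3.9062500000000002e-07	1345.6371212478721	False
pdz1-apm+par-complex	r5	1.9531250000000001e-07	2105.2904783482368	False
pdz1-apm+par-complex	r6	0	4000	True
pdz1-apm+par-complex	r6	0.0001	6.5712610253005899	False
pdz1-apm+par-complex	r6	5.0000000000000002e-05	13.134006205668847	False
pdz1-apm+par-complex	r6	2.5000000000000001e-05	26.233758254047057	False
pdz1-apm+par-complex	r6	1.2500000000000001e-05	52.328999540833365	False
pdz1-apm+par-complex	r6	6.2500000000000003e-06	104.09234492950192	False
pdz1-apm+par-complex	r6	3.1250000000000001e-06	205.83609306757867	False
pdz1-apm+par-complex	r6	1.5625000000000001e-06	401.69725528366882	False
pdz1-apm+par-complex	r6	7.8125000000000004e-07	760.48179117311099	False
pdz1-apm+par-complex	r6	3.9062500000000002e-07	1345.6371212478721	False
pdz1-apm+par-complex	r6	1.9531250000000001e-07	2105.2904783482368	False
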