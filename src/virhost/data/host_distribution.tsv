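order	n	Chordata	Invertebrate	Viridiplantae	Fungi	Bacteria	Primates	Rodentia	Carnivora	Artiodactyla	Chiroptera	Other Mammalia	Aves	Reptilia	Amphibia	Fish	Mammalia
Ortervirales	2764	92.0		8.0			85.9	0.9	0.9	2.0		0.7	1.6
Picornavirales	2647	74.2	12.2	13.6			40.2	4.1	4.2	14.5	2.6	1.7	3.9	0.9		2.0
Bunyavirales	1524	52.4	31.6	15.2	0.9		18.0	17.6		1.6	1.4	5.3	1.7	5.6		1.2
Tymovirales	1042		2.6	94.3	3.1
Reovirales	1034	52.9	33.8	9.7	3.6		9.9	1.3	2.9	9.0	5.5	3.6	9.6	1.3		10.0
Amarillovirales	817	85.2	14.8				54.0	9.7		10.0	4.0	4.2	1.7			1.6
Mononegavirales	758	57.5	27.8	11.3	3.3		11.3	6.5	4.0	5.4	11.5	2.4	9.0	1.6		5.9
Martellivirales	670	5.1	6.3	73.7	14.9											5.1
Nidovirales	622	94.4	5.6				4.8	5.3	5.6	36.3	17.4	5.6	13.5	5.8
Patatavirales	558			100.0
Ghabrivirales	393		14.0	9.9	76.1
Durnavirales	340	5.0		32.4	62.6											5.0
Stellavirales	296	100.0					10.1	12.8	8.4	33.1	5.1		16.2		4.4	9.8
Tolivirales	226		15.0	73.9	11.1
Hepelivirales	181	80.1	10.5	9.4			32.0	16.6		16.6		8.8	6.1
Sobelivirales	120		12.5	87.5
Blubervirales	108	100.0					75.9				14.8		9.3
Cryppavirales	80				100.0
Articulavirales	77	100.0											16.9			23.4	59.7
Jingchuvirales	61		100.0
Nodamuvirales	42		100.0
Ourlivirales	38			26.3	73.7
Wolframvirales	23				100.0
Mindivirales	22					100.0
Norzivirales	21					100.0
Serpentovirales	16			100.0
Muvirales	9		100.0
Yadokarivirales	7				100.0
Goujianvirales	3		100.0
Timlovirales	1					100.0
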