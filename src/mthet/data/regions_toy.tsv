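name	start	end	type	strand	frame_offset
D-loop	1	100	D-loop	H	
intergenic_101_150	101	150	intergenic	H	
toyCDS1	151	750	CDS	H	0
intergenic_751_800	751	800	intergenic	H	
toyT1	801	870	tRNA	H	
intergenic_871_900	871	900	intergenic	H	
toyR1	901	1200	rRNA	H	
intergenic_1201_1250	1201	1250	intergenic	H	
toyCDS2	1251	1850	CDS	L	0
intergenic_1851_2000	1851	2000	intergenic	H	
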