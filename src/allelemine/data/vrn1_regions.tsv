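region_name	start	end
promoter	0	2000
exon1	2000	2300
intron1	2300	12000
regulatory_2_8kb	4000	6800
core_region	5000	5600
exon2	12000	12200
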