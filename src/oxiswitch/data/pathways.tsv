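pathway_id	name	compound_code	neutral_mass
map00030	Pentose phosphate pathway	C01801	134.057909
map00030	Pentose phosphate pathway	C00672	214.024239
map00030	Pentose phosphate pathway	C00121	150.052823
map00030	Pentose phosphate pathway	C00257	196.058303
map00030	Pentose phosphate pathway	C00258	106.026609
map00040	Pentose and glucuronate interconversions	C01068	232.034804
map00040	Pentose and glucuronate interconversions	C00181	150.052823
map00040	Pentose and glucuronate interconversions	C00259	150.052823
map00040	Pentose and glucuronate interconversions	C00310	150.052823
map00040	Pentose and glucuronate interconversions	C00312	150.052823
map00040	Pentose and glucuronate interconversions	C00379	152.068473
map00040	Pentose and glucuronate interconversions	C00532	152.068473
map00040	Pentose and glucuronate interconversions	C00257	196.058303
map00040	Pentose and glucuronate interconversions	C00029	566.055020
map00040	Pentose and glucuronate interconversions	C00052	566.055020
map00040	Pentose and glucuronate interconversions	C00191	194.042653
map00040	Pentose and glucuronate interconversions	C00618	194.042653
map00040	Pentose and glucuronate interconversions	C02266	148.037173
map00053	Ascorbate and aldarate metabolism	C00137	180.063388
map00053	Ascorbate and aldarate metabolism	C00029	566.055020
map00053	Ascorbate and aldarate metabolism	C02670	176.032088
map00053	Ascorbate and aldarate metabolism	C00191	194.042653
map00053	Ascorbate and aldarate metabolism	C00800	196.058303
map00562	Inositol phosphate metabolism	C00137	180.063388
map00562	Inositol phosphate metabolism	C00222	88.016044
map00562	Inositol phosphate metabolism	C00191	194.042653
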