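rsid	chrom	pos	ref	alt	drug	evidence_level
rs3918290	chr1	97915614	C	T	fluorouracil/capecitabine	1A
rs55886062	chr1	97981343	A	C	fluorouracil/capecitabine	1A
rs67376798	chr1	97547947	T	A	fluorouracil/capecitabine	1A
rs75017182	chr1	98039419	G	C	fluorouracil/capecitabine	1A
rs1142345	chr6	18130918	T	C	mercaptopurine/thiopurines	1A
rs1800460	chr6	18139228	C	T	mercaptopurine/thiopurines	1A
rs1800462	chr6	18143955	C	G	mercaptopurine/thiopurines	1A
rs4148323	chr2	234669144	G	A	irinotecan	2A
rs3745274	chr19	41512841	G	T	cyclophosphamide	2A
rs1695	chr11	67352689	A	G	platinum compounds	2B
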