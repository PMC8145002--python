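gene	match_kind	match_value	tumor_type	tiers
BRAF	hotspot_aa	V600E	melanoma	T:I
BRAF	hotspot_aa	V600K	melanoma	T:I
KRAS	hotspot_aa	G12	colorectal	R:I
KRAS	hotspot_aa	G12	pancreatic	D:II;P:II
NRAS	hotspot_aa	G13	melanoma	T:II;P:I
NRAS	hotspot_aa	Q61	melanoma	T:II;P:I
KIT	hotspot_aa	L576P	melanoma	T:I
PIK3CA	hotspot_aa	H1047R	breast	T:I;P:II;R:II
PIK3CA	hotspot_aa	E545K	breast	T:I;P:II;R:II
EGFR	exon_region	exon 19 del	lung	T:I
EML4-ALK	fusion	EML4-ALK	lung	T:I;R:I
NCOA4-RET	fusion	NCOA4-RET	colorectal	T:II;P:II
BRCA2	gene_level	biallelic loss	ovarian	T:I
TP53	hotspot_aa	R175H	any	P:II
MSI	msi_status	MSI_H	colorectal	T:I;D:II;P:II
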