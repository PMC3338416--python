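target_id	gene	family	ec_class	oncoscore	regulation	name
PDGFRA	PDGFRA	enzyme	transferase	1.000	down	Alpha-type platelet-derived growth factor receptor
AR	AR	nuclear_receptor	none	1.000	none	Androgen receptor
TEK	TEK	enzyme	transferase	1.000	none	Angiopoietin-1 receptor
BRAF	BRAF	enzyme	transferase	1.000	none	B-Raf proto-oncogene serine/threonine-protein kinase
EGFR	EGFR	enzyme	transferase	1.000	none	Epidermal growth factor receptor
ESR1	ESR1	nuclear_receptor	none	1.000	none	Estrogen receptor
FLT3	FLT3	enzyme	transferase	1.000	none	FL cytokine receptor
MET	MET	enzyme	transferase	1.000	up	Hepatocyte growth factor receptor
KIT	KIT	enzyme	transferase	1.000	down	Mast/stem cell growth factor receptor
ABL1	ABL1	enzyme	transferase	1.000	none	Proto-oncogene tyrosine-protein kinase ABL1
SRC	SRC	enzyme	transferase	1.000	none	Proto-oncogene tyrosine-protein kinase Src
RAF1	RAF1	enzyme	transferase	1.000	none	RAF proto-oncogene serine/threonine-protein kinase
FLT1	FLT1	enzyme	transferase	1.000	none	Vascular endothelial growth factor receptor 1
FLT4	FLT4	enzyme	transferase	1.000	none	Vascular endothelial growth factor receptor 3
CDK2	CDK2	enzyme	transferase	0.999	none	Cell division protein kinase 2
NFATC1	NFATC1	other	none	0.999	none	Nuclear factor of activated T-cells, cytoplasmic 1
FKBP1A	FKBP1A	enzyme	isomerase	0.999	down	Peptidyl-prolyl cis-trans isomerase FKBP1A
STAT3	STAT3	other	none	0.999	none	Signal transducer and activator of transcription 3
CDK5	CDK5	enzyme	transferase	0.998	none	Cell division protein kinase 5
ESR2	ESR2	nuclear_receptor	none	0.998	none	Estrogen receptor beta
GSK3A	GSK3A	enzyme	transferase	0.996	none	Glycogen synthase kinase-3 alpha
FGR	FGR	enzyme	transferase	0.992	none	Proto-oncogene tyrosine-protein kinase FGR
MAP3K8	MAP3K8	enzyme	transferase	0.984	up	Mitogen-activated protein kinase kinase kinase 8
TRPC4	TRPC4	ion_channel	none	0.981	none	Short transient receptor potential channel 4
HDAC4	HDAC4	enzyme	hydrolase	0.975	none	Histone deacetylase 4
MAPK10	MAPK10	enzyme	transferase	0.974	none	Mitogen-activated protein kinase 10
TGFBR1	TGFBR1	enzyme	transferase	0.970	none	TGF-beta receptor type-1
MDM2	MDM2	enzyme	ligase	0.966	up	E3 ubiquitin-protein ligase Mdm2
HDAC7	HDAC7	enzyme	hydrolase	0.959	none	Histone deacetylase 7
PPARG	PPARG	nuclear_receptor	none	0.959	none	Peroxisome proliferator-activated receptor gamma
HDAC9	HDAC9	enzyme	hydrolase	0.953	down	Histone deacetylase 9
SCD	SCD	enzyme	oxidoreductase	0.940	up	Acyl-CoA desaturase
MAP2K1	MAP2K1	enzyme	transferase	0.895	none	Dual specificity mitogen-activated protein kinase kinase 1
HDAC1	HDAC1	enzyme	hydrolase	0.895	none	Histone deacetylase 1
HDAC6	HDAC6	enzyme	hydrolase	0.895	none	Histone deacetylase 6
DRD1	DRD1	GPCR	none	0.866	none	D(1A) dopamine receptor
S1PR1	S1PR1	GPCR	none	0.863	none	Sphingosine 1-phosphate receptor 1
STAT1	STAT1	other	none	0.824	up	Signal transducer and activator of transcription 1-alpha/beta
KLF5	KLF5	other	none	0.745	down	Krueppel-like factor 5
PARP1	PARP1	enzyme	transferase	0.711	none	Poly [ADP-ribose] polymerase 1
PIK3CD	PIK3CD	enzyme	transferase	0.708	none	Phosphatidylinositol-4,5-bisphosphate 3-kinase
CDK5R1	CDK5R1	other	none	0.701	none	Cyclin-dependent kinase 5 activator 1
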